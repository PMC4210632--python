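"""Gene-set perturbation testing, redundancy grouping, essential genes, clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from salmoarray.enrichment import (
    GeneSet,
    cluster_genes,
    essential_genes,
    gage_set_test,
    nonredundant_sets,
    per_gene_contrast_stats,
)
from salmoarray.errors import InsufficientDataError, InvalidDesignError
from salmoarray.qc import ExpressionMatrix
from salmoarray.simulate import (
    NoiseModel,
    build_design,
    make_pathway_scenario,
    simulate_intensities,
)

from conftest import log_ratio_expr


def scenario_contrasts(n_genes=600, n_sets=60, set_size=15, effect=1.0, bio=0.1, tech=0.05, seed=0):
    """Simulate a planted coordinated up-set and return (contrasts, sets)."""
    archs, sets = make_pathway_scenario(n_genes, n_sets, set_size, effect_size=effect, seed=seed)
    raw = simulate_intensities(
        build_design(6),
        archs,
        NoiseModel(biological_sd=bio, technical_sd=tech, flag_failure_rate=0.0, seed=seed + 1),
    )
    expr = log_ratio_expr(raw)
    expr.values.index = [p[: -len("_p1")] for p in expr.values.index]
    return per_gene_contrast_stats(expr, "feeding"), sets


class TestContrasts:
    def test_pair_column_combinatorics(self, noisy_expr):
        con = per_gene_contrast_stats(noisy_expr, "sac")
        assert con.shape[1] == 36  # 6 treat x 6 control arrays

    def test_identical_groups_give_zero_contrasts(self, design6):
        values = np.tile(np.arange(5.0)[:, None], 36)
        expr = ExpressionMatrix(
            values=pd.DataFrame(values, index=[f"p{i}" for i in range(5)], columns=design6.array_ids),
            samples=design6.samples.copy(),
        )
        con = per_gene_contrast_stats(expr, "sac")
        assert (con.to_numpy() == 0).all()

    def test_missing_group_rejected(self, noisy_expr):
        crippled = noisy_expr.drop_arrays(noisy_expr.arrays_for(cross="wild"))
        with pytest.raises(InvalidDesignError):
            per_gene_contrast_stats(crippled, "sac")

    def test_planted_up_set_has_identical_positive_contrasts(self):
        con, sets = scenario_contrasts(n_genes=200, n_sets=4, set_size=12, bio=0.0, tech=0.0, seed=5)
        planted = con.loc[sets["set001"]]
        assert (planted.to_numpy() > 0).all()
        # zero noise: every pair column carries the same planted offset
        assert np.allclose(planted.to_numpy(), 1.0)


class TestGageSetTest:
    def test_planted_set_is_unique_up_call(self):
        con, sets = scenario_contrasts(seed=10)
        up = gage_set_test(con, sets, "up", min_size=10, q_cut=0.1)
        sig = up[up["significant"]]
        assert list(sig["set_id"]) == ["set001"]
        down = gage_set_test(con, sets, "down")
        assert not down.loc[down["set_id"] == "set001", "significant"].any()

    def test_null_p_values_uniform(self):
        con, sets = scenario_contrasts(n_genes=1500, n_sets=150, set_size=20, effect=0.0, bio=0.25, seed=11)
        res = gage_set_test(con, sets, "up", min_size=10)
        ks = stats.kstest(res["p_value"].to_numpy(), "uniform")
        assert ks.pvalue > 0.01

    def test_sign_symmetry(self):
        con, sets = scenario_contrasts(n_genes=400, n_sets=30, seed=12)
        up_neg = gage_set_test(-con, sets, "up").set_index("set_id")["p_value"]
        down = gage_set_test(con, sets, "down").set_index("set_id")["p_value"]
        assert np.allclose(up_neg.sort_index(), down.sort_index())

    def test_two_way_detects_split_perturbation(self):
        con, sets = scenario_contrasts(n_genes=400, n_sets=30, seed=13, bio=0.05)
        # flip half of the planted genes down: no longer one-directional
        flip = sets["set001"][::2]
        con.loc[flip] = -con.loc[flip]
        two = gage_set_test(con, sets, "two_way").set_index("set_id")
        assert bool(two.loc["set001", "significant"])

    def test_excluded_functional_group_never_tested(self):
        con, _ = scenario_contrasts(n_genes=200, n_sets=2, set_size=12, seed=14)
        genes = list(con.index[:30])
        sets = [
            GeneSet("disease", "path", functional_group="Human Diseases", genes=tuple(genes[:15])),
            GeneSet("ok", "path", functional_group="Metabolism", genes=tuple(genes[15:])),
        ]
        res = gage_set_test(con, sets, "up", min_size=10, exclude_groups=("Human Diseases",))
        assert set(res["set_id"]) == {"ok"}

    def test_small_sets_skipped(self):
        con, _ = scenario_contrasts(n_genes=100, n_sets=2, set_size=12, seed=15)
        sets = {"tiny": list(con.index[:4]), "big": list(con.index[4:30])}
        res = gage_set_test(con, sets, "up", min_size=10)
        assert set(res["set_id"]) == {"big"}

    def test_stronger_coordination_never_less_significant(self):
        p_prev = 1.0
        for effect in (0.3, 0.6, 1.2):
            con, sets = scenario_contrasts(n_genes=300, n_sets=20, effect=effect, seed=16)
            res = gage_set_test(con, sets, "up").set_index("set_id")
            p = float(res.loc["set001", "p_value"])
            assert p <= p_prev
            p_prev = p


class TestNonredundantSets:
    def _results(self, ids, ps):
        return pd.DataFrame(
            {"set_id": ids, "p_value": ps, "significant": [True] * len(ids)}
        )

    def test_identical_sets_merge_to_one_representative(self):
        sets = {"A": ["g1", "g2", "g3"], "B": ["g1", "g2", "g3"]}
        out = nonredundant_sets(self._results(["A", "B"], [0.01, 0.001]), sets)
        assert out["group"].nunique() == 1
        assert set(out.loc[out["representative"], "set_id"]) == {"B"}

    def test_disjoint_sets_stay_separate(self):
        sets = {"A": ["g1", "g2"], "B": ["g3", "g4"]}
        out = nonredundant_sets(self._results(["A", "B"], [0.01, 0.02]), sets)
        assert out["group"].nunique() == 2

    def test_chain_merges_transitively(self):
        sets = {
            "A": ["g1", "g2", "g3", "g4"],
            "B": ["g3", "g4", "g5", "g6"],
            "C": ["g5", "g6", "g7", "g8"],
        }
        # A~B and B~C overlap at 50% of the smaller set; A∩C is empty
        out = nonredundant_sets(self._results(["A", "B", "C"], [0.01, 0.02, 0.03]), sets)
        assert out["group"].nunique() == 1
        # brute force transitive closure agrees
        assert len(set(out["group"])) == 1


class TestEssentialGenes:
    def test_selection_rules(self):
        # constant across 4 pair columns; grand mean exactly 0 by symmetry
        vals = np.array([0.0, 3.0, -3.0, 0.2, -0.2, 1.0, -1.0, 6.0, -6.0, 0.5, -0.5, 0.0])
        con = pd.DataFrame(
            np.tile(vals[:, None], 4), index=[f"g{i}" for i in range(12)], columns=list("abcd")
        )
        members = ("g0", "g1", "g2", "g5")
        out = essential_genes(con, ["S"], [GeneSet("S", genes=members)])
        got = set(out["gene_id"])
        sd = vals.std(ddof=1)  # brute-force oracle for the 1-SD rule
        expected = {g for g, v in zip(con.index, vals) if g in members and abs(v) > sd}
        assert got == expected
        assert "g0" not in got  # member at the grand mean
        assert {"g1", "g2"} <= got  # members beyond one SD
        assert "g7" not in got  # extreme but not in any significant set


class TestClusterGenes:
    def test_identical_rows_merge_first_at_zero_distance(self):
        rng = np.random.default_rng(17)
        rows = pd.DataFrame(rng.normal(size=(5, 8)), index=[f"g{i}" for i in range(5)])
        rows.loc["g1"] = rows.loc["g0"]
        order, z, _ = cluster_genes(rows)
        assert z[0, 2] == pytest.approx(0.0)
        assert {int(z[0, 0]), int(z[0, 1])} == {0, 1}

    def test_anticorrelated_rows_at_distance_two(self):
        rows = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0]], index=["g0", "g1"]
        )
        _, z, _ = cluster_genes(rows)
        assert z[0, 2] == pytest.approx(2.0)

    def test_average_linkage_matches_naive_oracle(self):
        rng = np.random.default_rng(18)
        rows = pd.DataFrame(rng.normal(size=(10, 12)), index=[f"g{i}" for i in range(10)])
        _, z, _ = cluster_genes(rows)
        # naive O(n^3) average linkage on the same distance matrix
        d = 1.0 - np.corrcoef(rows.to_numpy())
        clusters = {i: [i] for i in range(10)}
        heights = []
        next_id = 10
        while len(clusters) > 1:
            best = None
            for i in sorted(clusters):
                for j in sorted(clusters):
                    if i < j:
                        dij = np.mean([d[a, b] for a in clusters[i] for b in clusters[j]])
                        if best is None or dij < best[0]:
                            best = (dij, i, j)
            dij, i, j = best
            heights.append(dij)
            clusters[next_id] = clusters.pop(i) + clusters.pop(j)
            next_id += 1
        assert np.allclose(np.sort(z[:, 2]), np.sort(heights))

    def test_zero_variance_gene_reported_and_excluded(self):
        rng = np.random.default_rng(19)
        rows = pd.DataFrame(rng.normal(size=(4, 6)), index=["g0", "g1", "g2", "flat"])
        rows.loc["flat"] = 3.14
        order, _, excluded = cluster_genes(rows)
        assert excluded == ["flat"] and "flat" not in order

    def test_single_usable_gene_rejected(self):
        rows = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g0"])
        with pytest.raises(InsufficientDataError):
            cluster_genes(rows)
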