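"""Welch tests, signed fold changes, Venn partitioning, ANOVA + BH FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from salmoarray.diffexpr import (
    bh_fdr,
    dedupe_unique_genes,
    pairwise_de,
    signed_fold_change,
    union_across_stages,
    venn_partition,
    welch_anova,
    welch_anova_stats,
    welch_t,
)
from salmoarray.errors import InsufficientDataError
from salmoarray.io import annotation_from_truth
from salmoarray.simulate import (
    NoiseModel,
    TranscriptArchitecture,
    make_architectures,
    simulate_intensities,
)

from conftest import ZERO_NOISE, log_ratio_expr


def welch_reference(a, b):
    """Independently coded Welch-Satterthwaite t-test (oracle)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1) / na, b.var(ddof=1) / nb
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    return t, 2 * stats.t.sf(abs(t), df)


class TestWelchT:
    def test_identical_samples(self):
        t, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_matches_independent_formula(self):
        a, b = [1, 2, 3, 4, 5, 6], [3, 4, 5, 6, 7, 8]
        t, p = welch_t(a, b)
        t_ref, p_ref = welch_reference(a, b)
        assert t == pytest.approx(t_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_insufficient_replicates(self):
        with pytest.raises(InsufficientDataError):
            welch_t([1.0], [1.0, 2.0])

    def test_degenerate_zero_variance(self):
        assert welch_t([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)
        t, p = welch_t([3.0, 3.0], [2.0, 2.0])
        assert t == np.inf and p == 0.0

    def test_type_one_error_rate(self, design6):
        truth = make_architectures(10_000, effect_size=0.0, null_fraction=1.0, seed=31)
        raw = simulate_intensities(design6, truth, NoiseModel(flag_failure_rate=0.0, seed=32))
        expr = log_ratio_expr(raw)
        de = pairwise_de(expr, "sac")["wild_vs_domesticated"]
        frac = (de["p_value"] <= 0.01).mean()
        tol = 3 * np.sqrt(0.01 * 0.99 / len(de))
        assert abs(frac - 0.01) <= tol


class TestSignedFoldChange:
    @pytest.mark.parametrize(
        "ma,mb,expected", [(1.0, 0.0, 2.0), (0.0, 1.0, -2.0), (5.0, 5.0, 1.0)]
    )
    def test_examples(self, ma, mb, expected):
        assert signed_fold_change(ma, mb) == pytest.approx(expected)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        a=st.floats(-10, 10, allow_nan=False),
        b=st.floats(-10, 10, allow_nan=False),
    )
    def test_antisymmetric_and_bounded(self, a, b):
        f = signed_fold_change(a, b)
        g = signed_fold_change(b, a)
        assert abs(f) >= 1.0
        if f != 1.0 and g != 1.0:  # the fixed point is exempt
            assert f == pytest.approx(-g, rel=1e-12)


class TestPairwiseDE:
    def test_planted_fold_change_gates(self, design6):
        archs = [
            # log2(1.3001) just clears the 1.3 cut; log2(1.25) does not
            TranscriptArchitecture("gHit", ("gHit_p1",), 8.0, np.log2(1.3001), "additive"),
            TranscriptArchitecture("gNear", ("gNear_p1",), 8.0, np.log2(1.25), "additive"),
            TranscriptArchitecture("gNull", ("gNull_p1",), 8.0, 0.0, "additive"),
        ]
        raw = simulate_intensities(design6, archs, NoiseModel(**ZERO_NOISE, seed=33))
        de = pairwise_de(log_ratio_expr(raw), "sac")["wild_vs_domesticated"]
        de = de.set_index("probe_id")
        assert bool(de.loc["gHit_p1", "passes_strict"])
        assert not bool(de.loc["gNear_p1", "passes_strict"])
        assert bool(de.loc["gNear_p1", "passes_lenient"])
        assert de.loc["gHit_p1", "fold_change"] == pytest.approx(1.3001)

    def test_strict_subset_of_lenient(self, noisy_expr):
        for table in pairwise_de(noisy_expr, "feeding").values():
            assert not (table["passes_strict"] & ~table["passes_lenient"]).any()

    def test_power_at_high_snr(self, design6):
        truth = make_architectures(
            1000,
            mode_proportions={"additive": 1.0},
            effect_size=1.0,
            seed=34,
        )
        raw = simulate_intensities(
            design6, truth, NoiseModel(biological_sd=0.1, technical_sd=0.05, flag_failure_rate=0.0, seed=35)
        )
        de = pairwise_de(log_ratio_expr(raw), "feeding")["wild_vs_domesticated"]
        assert de["passes_strict"].mean() >= 0.95


class TestVenn:
    def test_small_example(self):
        regions = venn_partition({"A": ["a", "b"], "B": ["b", "c"], "C": []})
        assert regions[("A",)] == {"a"}
        assert regions[("A", "B")] == {"b"}
        assert regions[("B",)] == {"c"}
        assert all(not v for k, v in regions.items() if k not in [("A",), ("B",), ("A", "B")])

    def test_identical_lists_all_in_triple_intersection(self):
        regions = venn_partition({"A": ["x", "y"], "B": ["x", "y"], "C": ["x", "y"]})
        assert regions[("A", "B", "C")] == {"x", "y"}
        assert sum(len(v) for v in regions.values()) == 2

    def test_random_lists_match_bruteforce(self):
        rng = np.random.default_rng(36)
        universe = [f"id{i}" for i in range(1200)]
        lists = {
            "A": list(rng.choice(universe, 176, replace=False)),
            "B": list(rng.choice(universe, 300, replace=False)),
            "C": list(rng.choice(universe, 411, replace=False)),
        }
        regions = venn_partition(lists)
        union = set().union(*map(set, lists.values()))
        assert sum(len(v) for v in regions.values()) == len(union)
        # brute force: each id goes to exactly the region of its memberships
        for x in union:
            key = tuple(sorted(n for n, ids in lists.items() if x in set(ids)))
            assert x in regions[key]

    def test_union_across_stages(self):
        merged = union_across_stages({"w_d": {"a"}}, {"w_d": {"b"}, "w_h": {"c"}})
        assert merged == {"w_d": {"a", "b"}, "w_h": {"c"}}


class TestWelchAnova:
    def test_identical_groups_give_p_one(self):
        g = np.array([[1.0, 2.0, 3.0]])
        f, p = welch_anova_stats([g, g, g])
        assert f[0] == pytest.approx(0.0) and p[0] == pytest.approx(1.0)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(37)
        groups = [rng.normal(i * 0.3, 1.0 + i, (15, 6)) for i in range(3)]
        f, p = welch_anova_stats(groups)
        for row in range(15):
            long = pd.DataFrame(
                {
                    "y": np.concatenate([g[row] for g in groups]),
                    "grp": np.repeat(["a", "b", "c"], 6),
                }
            )
            ref = pingouin.welch_anova(data=long, dv="y", between="grp")
            assert f[row] == pytest.approx(float(ref["F"][0]), rel=1e-9)
            assert p[row] == pytest.approx(float(ref["p_unc"][0]), rel=1e-9)

    def test_two_groups_reduce_to_welch_t(self):
        rng = np.random.default_rng(38)
        a, b = rng.normal(0, 1, (10, 6)), rng.normal(0.5, 2, (10, 5))
        f, p_f = welch_anova_stats([a, b])
        for row in range(10):
            t, p_t = welch_t(a[row], b[row])
            assert f[row] == pytest.approx(t**2, rel=1e-9)
            assert p_f[row] == pytest.approx(p_t, rel=1e-9)

    def test_small_group_rejected(self, noisy_expr):
        dropped = noisy_expr.drop_arrays([a for a in noisy_expr.arrays_for(cross="wild", stage="sac")][1:])
        with pytest.raises(InsufficientDataError):
            welch_anova(dropped, "sac")


class TestBHFdr:
    def test_hand_computed_stepup(self):
        q, passes = bh_fdr([0.01, 0.02, 0.03, 0.04], q_cut=0.10)
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])
        assert passes.all()

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(ps=st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=40))
    def test_monotone_and_dominates_p(self, ps):
        q, _ = bh_fdr(ps)
        p = np.asarray(ps)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-12).all()


class TestDedupe:
    def _annotation(self):
        return pd.DataFrame(
            {
                "probe_id": ["p1", "p2", "p3"],
                "gene_id": ["g1", "g1", "g2"],
                "annotated": [True, True, False],
            }
        )

    def test_most_significant_probe_wins(self):
        res = pd.DataFrame({"probe_id": ["p1", "p2"], "p_value": [0.005, 0.001]})
        out = dedupe_unique_genes(res, self._annotation())
        assert list(out["probe_id"]) == ["p2"]

    def test_unannotated_probe_excluded(self):
        res = pd.DataFrame({"probe_id": ["p3"], "p_value": [1e-9]})
        assert dedupe_unique_genes(res, self._annotation()).empty

    def test_tie_broken_by_probe_id(self):
        res = pd.DataFrame({"probe_id": ["p2", "p1"], "p_value": [0.01, 0.01]})
        out = dedupe_unique_genes(res, self._annotation())
        assert list(out["probe_id"]) == ["p1"]

    def test_counts_match_planted_truth(self, design6):
        truth = make_architectures(
            500, null_fraction=0.4, duplicate_probe_fraction=0.2, annotated_fraction=0.8, seed=39
        )
        raw = simulate_intensities(design6, truth, NoiseModel(seed=40))
        expr = log_ratio_expr(raw)
        anova = welch_anova(expr, "feeding")
        ann = annotation_from_truth(truth)
        unique = dedupe_unique_genes(anova, ann)
        expected = {a.gene_id for a in truth if a.annotated}
        assert set(unique["gene_id"]) == expected
        assert len(unique) == len(expected)
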