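"""Reproducible evaluation scenarios for the pipeline's operating characteristics.

Each function simulates a study-shaped data set (3 crosses x 2 stages x 6
replicate arrays unless noted), runs the relevant pipeline stages and measures
how well the planted truth is recovered: inheritance-mode classification
accuracy, Welch-test type-I error and BH false-discovery control, lowess
dye-bias removal, and detection of a single coordinated pathway among null
pathways.  All randomness derives from the `seed` argument.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import diffexpr, enrichment, inheritance, qc
from .simulate import (
    FEEDING_FRY_MODE_MIX,
    NoiseModel,
    build_design,
    make_architectures,
    make_pathway_scenario,
    simulate_intensities,
)


def _sub_seed(seed: int, k: int) -> int:
    return (seed * 1009 + k) % (2**31 - 1)


def inheritance_mode_recovery(
    seed: int,
    n_genes: int = 2000,
    effect_size: float = 1.0,
    biological_sd: float = 0.25,
    technical_sd: float = 0.05,
) -> dict:
    """Classify planted inheritance modes through the full QC path.

    Simulates `n_genes` differentially expressed genes with the feeding-fry
    mode mix (45 / 42.2 / 6.1 / 6.7% additive / maternal / paternal /
    overdominant), normalises, filters probes, computes alpha and delta per
    gene and compares the classified mode against the planted one.
    """
    design = build_design(6)
    truth = make_architectures(
        n_genes,
        mode_proportions=FEEDING_FRY_MODE_MIX,
        effect_size=effect_size,
        seed=_sub_seed(seed, 1),
    )
    noise = NoiseModel(
        biological_sd=biological_sd,
        technical_sd=technical_sd,
        flag_failure_rate=0.05,
        seed=_sub_seed(seed, 2),
    )
    raw = simulate_intensities(design, truth, noise)
    expr = qc.lowess_normalize(qc.floor_intensities(raw))
    retained = qc.filter_probes(raw.flags, design)
    expr = expr.subset_probes(retained)
    gene_ids = [p.rsplit("_p", 1)[0] for p in expr.values.index]
    rec = inheritance.inheritance_table(expr, "feeding", list(expr.values.index), gene_ids=gene_ids)
    planted = {a.gene_id: a.mode for a in truth}
    hits = [planted[g] == m for g, m in zip(rec["gene_id"], rec["mode"])]
    props = inheritance.summarize_proportions(rec).set_index("mode")["fraction"]
    return {
        "recovery_pct": 100.0 * float(np.mean(hits)),
        "fractions_pct": {m: 100.0 * float(props[m]) for m in FEEDING_FRY_MODE_MIX},
        "planted_pct": {m: 100.0 * v for m, v in FEEDING_FRY_MODE_MIX.items()},
        "n": len(rec),
    }


def welch_type1_error(seed: int, n_probes: int = 10_000) -> dict:
    """Fraction of null probes with Welch-t p <= 0.01 (wild vs domesticated)."""
    design = build_design(6)
    truth = make_architectures(n_probes, effect_size=0.0, null_fraction=1.0, seed=_sub_seed(seed, 3))
    raw = simulate_intensities(design, truth, NoiseModel(flag_failure_rate=0.0, seed=_sub_seed(seed, 4)))
    expr = qc.log_ratios(raw)
    de = diffexpr.pairwise_de(expr, "sac")["wild_vs_domesticated"]
    frac = float((de["p_value"] <= 0.01).mean())
    return {
        "rate": frac,
        "nominal": 0.01,
        "binomial_3sd": 3.0 * math.sqrt(0.01 * 0.99 / len(de)),
        "n": len(de),
    }


def anova_false_discovery(seed: int, n_probes: int = 10_000, n_reps: int = 20) -> dict:
    """Mean false-discovery proportion of BH-ANOVA (q <= 0.10) on null data."""
    design = build_design(6)
    fdps = []
    for r in range(n_reps):
        truth = make_architectures(
            n_probes, effect_size=0.0, null_fraction=1.0, seed=_sub_seed(seed, 10 + 2 * r)
        )
        raw = simulate_intensities(
            design, truth, NoiseModel(flag_failure_rate=0.0, seed=_sub_seed(seed, 11 + 2 * r))
        )
        expr = qc.log_ratios(raw)
        anova = diffexpr.welch_anova(expr, "feeding")
        _, passes = diffexpr.bh_fdr(anova["p_value"], q_cut=0.10)
        n_called = int(passes.sum())
        fdps.append(1.0 if n_called else 0.0)  # every call on null data is false
    fdps = np.asarray(fdps)
    return {
        "mean_fdp": float(fdps.mean()),
        "mc_se": float(fdps.std(ddof=1) / math.sqrt(n_reps)) if n_reps > 1 else 0.0,
        "n": n_probes * n_reps,
    }


def lowess_bias_removal(seed: int, n_probes: int = 3000, n_arrays_checked: int = 6) -> dict:
    """Max |refit| after removing an injected smooth dye bias 0.5*sin(A/4).

    The scenario is bias-only (noise SDs 0): it isolates the systematic
    intensity-dependent component the normalisation is defined to remove.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

    design = build_design(6)
    truth = make_architectures(
        n_probes, effect_size=0.0, null_fraction=1.0, baseline_sd=2.0, seed=_sub_seed(seed, 50)
    )
    noise = NoiseModel(
        biological_sd=0.0,
        technical_sd=0.0,
        flag_failure_rate=0.0,
        dye_bias=lambda a: 0.5 * np.sin(a / 4.0),
        seed=_sub_seed(seed, 51),
    )
    raw = simulate_intensities(design, truth, noise)
    floored = qc.floor_intensities(raw)
    expr = qc.lowess_normalize(floored)
    a = 0.5 * (np.log2(floored.sample.to_numpy()) + np.log2(floored.reference.to_numpy()))
    worst = 0.0
    for j in range(min(n_arrays_checked, a.shape[1])):
        refit = sm_lowess(expr.values.to_numpy()[:, j], a[:, j], frac=0.2, it=3, return_sorted=False)
        worst = max(worst, float(np.abs(refit).max()))
    return {"max_abs_refit": worst, "n": n_probes}


def probe_filter_bruteforce_agreement(seed: int, n_probes: int = 1000) -> dict:
    """Exact agreement of the vectorised probe filter with direct enumeration."""
    design = build_design(6)
    rng = np.random.default_rng(_sub_seed(seed, 60))
    flags = pd.DataFrame(
        rng.random((n_probes, 36)) < rng.uniform(0.3, 0.9, size=(n_probes, 1)),
        index=[f"p{i}" for i in range(n_probes)],
        columns=design.array_ids,
    )
    fast = set(qc.filter_probes(flags, design))
    brute = set()
    for probe in flags.index:
        ok = 0
        for cross, stage in design.groups:
            arrays = design.arrays_for(cross=cross, stage=stage)
            if sum(bool(flags.loc[probe, a]) for a in arrays) >= math.ceil(0.75 * len(arrays)):
                ok += 1
        if ok >= 2:
            brute.add(probe)
    return {"agreement": float(fast == brute), "n": n_probes}


def venn_bruteforce_agreement(seed: int) -> dict:
    """Exact agreement of the Venn partition with per-id membership checks."""
    rng = np.random.default_rng(_sub_seed(seed, 61))
    universe = [f"t{i}" for i in range(1500)]
    lists = {
        "wild_vs_dom": set(rng.choice(universe, 176, replace=False)),
        "wild_vs_hyb": set(rng.choice(universe, 300, replace=False)),
        "hyb_vs_dom": set(rng.choice(universe, 411, replace=False)),
    }
    regions = diffexpr.venn_partition(lists)
    union = set().union(*lists.values())
    ok = sum(len(v) for v in regions.values()) == len(union)
    for x in union:
        key = tuple(sorted(n for n, ids in lists.items() if x in ids))
        ok = ok and (x in regions[key])
    return {"agreement": float(ok), "n": len(union)}


def pathway_detection(
    seed: int,
    n_reps: int = 20,
    n_genes: int = 2000,
    n_sets: int = 200,
    set_size: int = 25,
    effect_size: float = 1.0,
) -> dict:
    """Detection of one planted coordinated pathway among null pathways.

    Per replicate, the planted set's genes all move `effect_size` log2 units
    up in the domesticated cross (wild as control) at low noise; success means
    the planted set is the unique q <= 0.1 call of the up-direction test.
    """
    design = build_design(6)
    unique_calls = 0
    detected = 0
    for r in range(n_reps):
        archs, sets = make_pathway_scenario(
            n_genes, n_sets, set_size, effect_size=effect_size, direction="up", seed=_sub_seed(seed, 100 + 2 * r)
        )
        noise = NoiseModel(
            biological_sd=0.1, technical_sd=0.05, flag_failure_rate=0.0, seed=_sub_seed(seed, 101 + 2 * r)
        )
        raw = simulate_intensities(design, archs, noise)
        expr = qc.log_ratios(raw)
        expr.values.index = [p.rsplit("_p", 1)[0] for p in expr.values.index]
        contrasts = enrichment.per_gene_contrast_stats(expr, "feeding")
        up = enrichment.gage_set_test(contrasts, sets, "up", min_size=10, q_cut=0.1)
        called = list(up.loc[up["significant"], "set_id"])
        detected += "set001" in called
        unique_calls += called == ["set001"]
    return {
        "unique_detection_pct": 100.0 * unique_calls / n_reps,
        "detection_pct": 100.0 * detected / n_reps,
        "n": n_reps,
    }


def worked_micro_examples() -> dict:
    """Small closed-form checks of the arithmetic conventions."""
    rec = pd.DataFrame({"mode": ["additive"] * 12 + ["maternal_dominant"] * 13, "ratio": [0.0] * 12 + [1.0] * 13})
    props = inheritance.summarize_proportions(rec).set_index("mode")["fraction"]
    ratio_one = inheritance.compute_alpha_delta(
        pd.DataFrame({"gene_id": ["g"], "W": [10.0], "H": [6.0], "D": [6.0]})
    )["ratio"][0]
    return {
        "sac_additive_pct": 100.0 * float(props["additive"]),
        "sac_maternal_pct": 100.0 * float(props["maternal_dominant"]),
        "signed_fc_for_half_ratio": float(diffexpr.signed_fold_change(0.0, 1.0)),
        "delta_alpha_at_complete_maternal_dominance": float(ratio_one),
    }
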