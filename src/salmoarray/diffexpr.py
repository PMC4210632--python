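"""Per-probe differential expression between crosses.

Pairwise Welch t-tests (unpaired, unequal variance) with a signed fold-change
convention (ratios below 1 reported as -1/ratio), Venn partitioning of the
comparison lists, Welch's one-way ANOVA across the three crosses with
Benjamini-Hochberg FDR control, and collapsing of multi-probe genes to the
most significant probe.  Life stages are always analysed separately; the
strict lists (p <= 0.01 and |FC| >= 1.3) deliberately carry no
multiple-testing correction, matching how such comparison lists are
conventionally drawn up for Venn diagrams.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientDataError, InvalidDesignError
from .qc import ExpressionMatrix

COMPARISONS = (
    ("wild", "domesticated"),
    ("wild", "hybrid"),
    ("hybrid", "domesticated"),
)


def _welch_arrays(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Welch t over the last axis, with zero-variance conventions."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise InsufficientDataError("Welch t-test needs >= 2 replicates per group")
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    degenerate = (va == 0) & (vb == 0)
    if degenerate.any():
        equal = degenerate & (a.mean(axis=1) == b.mean(axis=1))
        t[equal] = 0.0
        p[equal] = 1.0
        unequal = degenerate & ~equal
        t[unequal] = np.sign(a.mean(axis=1) - b.mean(axis=1))[unequal] * np.inf
        p[unequal] = 0.0
    return t, p


def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Welch t-test (unpaired, unequal variance) for two samples."""
    t, p = _welch_arrays(np.asarray(a, dtype=float)[None, :], np.asarray(b, dtype=float)[None, :])
    return float(t[0]), float(p[0])


def signed_fold_change(mean_a, mean_b):
    """Linear fold change with the signed-ratio convention.

    r = 2**(mean_a - mean_b); ratios below 1 are reported as -1/r so that a
    2-fold drop reads -2.0 rather than 0.5.  Works elementwise on arrays.
    """
    r = np.exp2(np.asarray(mean_a, dtype=float) - np.asarray(mean_b, dtype=float))
    out = np.where(r >= 1.0, r, -1.0 / r)
    return out if out.ndim else float(out)


def pairwise_de(
    expr: ExpressionMatrix,
    stage: str,
    p_strict: float = 0.01,
    fc_strict: float = 1.3,
    p_lenient: float = 0.05,
    mean_scale: str = "log2",
) -> dict[str, pd.DataFrame]:
    """Welch t-tests for the three cross comparisons within one life stage.

    Returns one table per comparison with p-values, group means, signed fold
    changes and the strict (p <= `p_strict`, |FC| >= `fc_strict`) and lenient
    (p <= `p_lenient`, no fold-change gate) selection flags.  ``mean_scale``
    controls whether fold changes derive from log2 group means ("log2") or
    from means of linearised intensities ("linear").
    """
    if mean_scale not in ("log2", "linear"):
        raise InvalidDesignError(f"unknown mean_scale {mean_scale!r}")
    out: dict[str, pd.DataFrame] = {}
    for ga, gb in COMPARISONS:
        cols_a = expr.arrays_for(cross=ga, stage=stage)
        cols_b = expr.arrays_for(cross=gb, stage=stage)
        if not cols_a or not cols_b:
            raise InvalidDesignError(f"stage {stage!r}: missing group {ga if not cols_a else gb!r}")
        a = expr.values[cols_a].to_numpy(dtype=float)
        b = expr.values[cols_b].to_numpy(dtype=float)
        t, p = _welch_arrays(a, b)
        mean_a = a.mean(axis=1)
        mean_b = b.mean(axis=1)
        if mean_scale == "log2":
            fc = signed_fold_change(mean_a, mean_b)
        else:
            ra = np.exp2(a).mean(axis=1) / np.exp2(b).mean(axis=1)
            fc = np.where(ra >= 1.0, ra, -1.0 / ra)
        table = pd.DataFrame(
            {
                "probe_id": expr.values.index,
                "comparison": f"{ga}_vs_{gb}",
                "t": t,
                "p_value": p,
                "mean_a": mean_a,
                "mean_b": mean_b,
                "fold_change": fc,
                "passes_strict": (p <= p_strict) & (np.abs(fc) >= fc_strict),
                "passes_lenient": p <= p_lenient,
            }
        )
        out[f"{ga}_vs_{gb}"] = table
    return out


def venn_partition(lists: Mapping[str, Iterable[str]]) -> dict[tuple[str, ...], set[str]]:
    """Disjoint membership regions of the given id lists.

    Keys are sorted tuples of the list names an id belongs to; every id in the
    union appears in exactly one region.
    """
    sets = {name: set(ids) for name, ids in lists.items()}
    names = sorted(sets)
    regions: dict[tuple[str, ...], set[str]] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo)) if combo else set()
            outside = set.union(set(), *(sets[n] for n in names if n not in combo))
            regions[combo] = inside - outside
    return regions


def union_across_stages(
    lists_a: Mapping[str, Iterable[str]],
    lists_b: Mapping[str, Iterable[str]],
) -> dict[str, set[str]]:
    """Per-comparison union of the stage-specific id lists."""
    keys = set(lists_a) | set(lists_b)
    return {k: set(lists_a.get(k, ())) | set(lists_b.get(k, ())) for k in keys}


def welch_anova_stats(groups: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Welch one-way ANOVA over rows.

    `groups` is a sequence of (probes x n_i) arrays, one per group.  Returns
    (F, p) using the Welch-Satterthwaite F* approximation with
    df1 = k - 1 and df2 from the group weight dispersion.
    """
    k = len(groups)
    if k < 2:
        raise InsufficientDataError("Welch ANOVA needs >= 2 groups")
    mats = [np.atleast_2d(np.asarray(g, dtype=float)) for g in groups]
    ns = np.asarray([m.shape[1] for m in mats])
    if (ns < 2).any():
        raise InsufficientDataError("every group needs >= 2 replicates")
    means = np.stack([m.mean(axis=1) for m in mats])  # k x probes
    varis = np.stack([m.var(axis=1, ddof=1) for m in mats])
    # Guard partially-degenerate rows (one constant group) against inf weights.
    varis_safe = np.where(varis == 0.0, np.finfo(float).tiny, varis)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = ns[:, None] / varis_safe  # k x probes
        w_sum = w.sum(axis=0)
        grand = (w * means).sum(axis=0) / w_sum
        a = (w * (means - grand) ** 2).sum(axis=0) / (k - 1)
        disp = (((1.0 - w / w_sum) ** 2) / (ns[:, None] - 1)).sum(axis=0)
        b = 1.0 + 2.0 * (k - 2) / (k**2 - 1.0) * disp
        f = a / b
        df2 = (k**2 - 1.0) / (3.0 * disp)
    p = stats.f.sf(f, k - 1, df2)
    # All-groups-constant rows: no evidence of difference by convention.
    degenerate = (varis == 0).all(axis=0)
    if degenerate.any():
        same = degenerate & (np.ptp(means, axis=0) == 0)
        f[same] = 0.0
        p[same] = 1.0
        diff = degenerate & ~same
        f[diff] = np.inf
        p[diff] = 0.0
    return f, p


def welch_anova(expr: ExpressionMatrix, stage: str) -> pd.DataFrame:
    """Per-probe Welch ANOVA across the three crosses of one stage."""
    groups, mean_cols = [], {}
    for cross in ("wild", "hybrid", "domesticated"):
        cols = expr.arrays_for(cross=cross, stage=stage)
        if len(cols) < 2:
            raise InsufficientDataError(f"stage {stage!r}: group {cross!r} has < 2 arrays")
        g = expr.values[cols].to_numpy(dtype=float)
        groups.append(g)
        mean_cols[f"mean_{cross}"] = g.mean(axis=1)
    f, p = welch_anova_stats(groups)
    return pd.DataFrame(
        {"probe_id": expr.values.index, "F": f, "p_value": p, **mean_cols}
    )


def bh_fdr(p_values: Sequence[float], q_cut: float = 0.10) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and the q <= `q_cut` flags."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q, q <= q_cut


def dedupe_unique_genes(
    results: pd.DataFrame,
    annotation: pd.DataFrame,
    p_column: str = "p_value",
) -> pd.DataFrame:
    """Collapse probe-level results to unique annotated genes.

    `annotation` maps probe_id -> gene_id with an `annotated` flag; probes
    without annotation are removed, and for genes probed more than once the
    most significant probe wins (ties broken by lexicographic probe id).
    """
    ann = annotation.set_index("probe_id") if "probe_id" in annotation.columns else annotation
    merged = results.join(ann[["gene_id", "annotated"]], on="probe_id", how="inner")
    merged = merged[merged["annotated"].astype(bool)]
    merged = merged.sort_values([p_column, "probe_id"], kind="mergesort")
    return merged.drop_duplicates(subset="gene_id", keep="first").reset_index(drop=True)
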