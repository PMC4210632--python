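"""Additivity/dominance classification of transcript inheritance in hybrids.

For each gene the additive parameter alpha = (wild - domesticated) / 2 and the
dominance deviation delta = (wild + domesticated) / 2 - hybrid are computed
from mean normalised log2 expression values.  The ratio delta/alpha places the
hybrid relative to its parents: 0 is perfect within-locus additivity, +1 is
complete dominance toward the domesticated dam (indistinguishable here from a
maternal effect, as only one hybrid cross direction exists), -1 complete
dominance toward the wild sire, and values beyond +-1.5 overdominance.

Interval convention (closed lower, open upper; the strict published
inequalities leave boundaries undefined, and boundaries have probability zero
on continuous data):

    additive            -0.5 <= delta/alpha < 0.5
    maternal_dominant    0.5 <= delta/alpha < 1.5
    paternal_dominant   -1.5 <= delta/alpha < -0.5
    overdominant         otherwise (alpha = 0 with delta != 0 included)
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EmptyInputError, InsufficientDataError
from .qc import ExpressionMatrix

MODE_ORDER = ("additive", "maternal_dominant", "paternal_dominant", "overdominant")


def compute_group_means(
    expr: ExpressionMatrix,
    stage: str,
    ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-row W/H/D mean log2 expression for one life stage."""
    values = expr.values if ids is None else expr.values.loc[list(ids)]
    out = {"gene_id": values.index}
    for label, cross in (("W", "wild"), ("H", "hybrid"), ("D", "domesticated")):
        cols = expr.arrays_for(cross=cross, stage=stage)
        if not cols:
            raise InsufficientDataError(f"stage {stage!r}: no arrays for {cross}")
        out[label] = values[cols].mean(axis=1).to_numpy()
    return pd.DataFrame(out)


def compute_alpha_delta(means: pd.DataFrame) -> pd.DataFrame:
    """alpha, delta and their ratio from W/H/D means.

    ``ratio`` is NaN with ``ratio_undefined`` set when alpha is exactly 0.
    """
    w = means["W"].to_numpy(dtype=float)
    h = means["H"].to_numpy(dtype=float)
    d = means["D"].to_numpy(dtype=float)
    alpha = (w - d) / 2.0
    delta = (w + d) / 2.0 - h
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(alpha != 0.0, delta / alpha, np.nan)
    out = means.copy()
    out["alpha"] = alpha
    out["delta"] = delta
    out["ratio"] = ratio
    out["ratio_undefined"] = alpha == 0.0
    return out


def classify_mode(records: pd.DataFrame) -> pd.DataFrame:
    """Assign every record exactly one inheritance mode."""
    alpha = records["alpha"].to_numpy(dtype=float)
    delta = records["delta"].to_numpy(dtype=float)
    ratio = records["ratio"].to_numpy(dtype=float)
    mode = np.full(len(records), "overdominant", dtype=object)
    with np.errstate(invalid="ignore"):
        mode[(ratio >= -0.5) & (ratio < 0.5)] = "additive"
        mode[(ratio >= 0.5) & (ratio < 1.5)] = "maternal_dominant"
        mode[(ratio >= -1.5) & (ratio < -0.5)] = "paternal_dominant"
    undefined = alpha == 0.0
    mode[undefined & (delta == 0.0)] = "additive"
    mode[undefined & (delta != 0.0)] = "overdominant"
    out = records.copy()
    out["mode"] = mode
    return out


def summarize_proportions(records: pd.DataFrame) -> pd.DataFrame:
    """Counts and fractions per inheritance mode (per stage when present).

    Overdominant records are additionally split by which parent the hybrid
    overshoots: ratio >= 1.5 lies beyond the domesticated dam (maternal side),
    ratio <= -1.5 beyond the wild sire (paternal side).
    """
    if records.empty:
        raise EmptyInputError("no inheritance records to summarise")
    frames = []
    grouped = records.groupby("stage") if "stage" in records.columns else [(None, records)]
    for stage, grp in grouped:
        n = len(grp)
        counts = grp["mode"].value_counts()
        ratio = grp["ratio"].to_numpy(dtype=float)
        over = grp["mode"] == "overdominant"
        with np.errstate(invalid="ignore"):
            maternal_side = int((over & (ratio >= 1.5)).sum())
            paternal_side = int((over & (ratio <= -1.5)).sum())
        for m in MODE_ORDER:
            c = int(counts.get(m, 0))
            frames.append(
                {
                    "stage": stage,
                    "mode": m,
                    "count": c,
                    "fraction": c / n,
                    "overdominant_maternal_side": maternal_side if m == "overdominant" else 0,
                    "overdominant_paternal_side": paternal_side if m == "overdominant" else 0,
                }
            )
    return pd.DataFrame(frames)


def inheritance_table(
    expr: ExpressionMatrix,
    stage: str,
    ids: Sequence[str] | None = None,
    gene_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Full per-gene inheritance record for one stage.

    ``ids`` selects expression rows (probe ids); ``gene_ids`` optionally
    relabels them (after unique-gene deduplication upstream).
    """
    means = compute_group_means(expr, stage, ids)
    if gene_ids is not None:
        means["gene_id"] = list(gene_ids)
    rec = classify_mode(compute_alpha_delta(means))
    rec["stage"] = stage
    return rec


def export_scatter_table(
    expr: ExpressionMatrix,
    stage: str,
    ids: Sequence[str],
    plot_limit: float = 5.0,
) -> pd.DataFrame:
    """Scatter-plot table of alpha and delta/alpha with replicate-based SDs.

    Per replicate index r, alpha and delta/alpha are recomputed from the r-th
    array of each group (groups truncated to the smallest group size) and the
    per-axis SD across those replicate estimates is reported.  Rows whose
    |ratio| exceeds ``plot_limit`` are flagged as excluded from the plot but
    retained in the table.
    """
    rec = inheritance_table(expr, stage, ids)
    cols = {c: expr.arrays_for(cross=c, stage=stage) for c in ("wild", "hybrid", "domesticated")}
    n_rep = min(len(v) for v in cols.values())
    values = expr.values.loc[list(ids)]
    alphas, ratios = [], []
    for r in range(n_rep):
        w = values[cols["wild"][r]].to_numpy(dtype=float)
        h = values[cols["hybrid"][r]].to_numpy(dtype=float)
        d = values[cols["domesticated"][r]].to_numpy(dtype=float)
        a = (w - d) / 2.0
        dl = (w + d) / 2.0 - h
        with np.errstate(divide="ignore", invalid="ignore"):
            alphas.append(a)
            ratios.append(np.where(a != 0.0, dl / a, np.nan))
    alpha_mat = np.stack(alphas)
    ratio_mat = np.stack(ratios)
    rec["alpha_sd"] = alpha_mat.std(axis=0, ddof=1)
    rec["ratio_sd"] = ratio_mat.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore"):
        rec["excluded_from_plot"] = np.abs(rec["ratio"].to_numpy(dtype=float)) > plot_limit
    return rec
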