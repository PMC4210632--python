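"""Quality filtering and normalisation of two-channel intensities.

Raw background-subtracted intensities are floored at 1, converted to M/A
coordinates (M = log2 sample/reference, A = mean log2 intensity) and
lowess-normalised per array to remove intensity-dependent dye bias.  Probes
are retained only when their detection flag ("positive and significant"
against background) holds on at least 75% of the arrays of at least two
experimental groups; arrays far from the rest in principal-component space
are flagged for the analyst (never dropped automatically).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .errors import DimensionError, InsufficientDataError
from .simulate import ExperimentDesign, RawIntensityData


@dataclass(frozen=True, eq=False)
class ExpressionMatrix:
    """Normalised log2(sample/reference) values for retained probes."""

    values: pd.DataFrame  # probes x arrays
    samples: pd.DataFrame  # array_id, cross, stage (analysed arrays only)
    excluded_arrays: tuple[tuple[str, str], ...] = ()  # (array_id, reason)

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.samples["array_id"]):
            raise DimensionError("expression columns must match the sample sheet")
        if self.values.isna().any().any():
            raise DimensionError("retained probes may not contain missing values")

    def arrays_for(self, cross: str | None = None, stage: str | None = None) -> list[str]:
        m = pd.Series(True, index=self.samples.index)
        if cross is not None:
            m &= self.samples["cross"] == cross
        if stage is not None:
            m &= self.samples["stage"] == stage
        return list(self.samples.loc[m, "array_id"])

    def subset_probes(self, probe_ids) -> "ExpressionMatrix":
        return replace(self, values=self.values.loc[list(probe_ids)])

    def drop_arrays(self, array_ids, reason: str = "excluded") -> "ExpressionMatrix":
        drop = set(array_ids)
        keep = [a for a in self.values.columns if a not in drop]
        return ExpressionMatrix(
            values=self.values[keep],
            samples=self.samples[self.samples["array_id"].isin(keep)].reset_index(drop=True),
            excluded_arrays=self.excluded_arrays + tuple((a, reason) for a in sorted(drop)),
        )


def floor_intensities(raw: RawIntensityData, floor: float = 1.0) -> RawIntensityData:
    """Replace channel intensities below `floor` (default 1) by `floor`."""
    return replace(
        raw,
        sample=raw.sample.clip(lower=floor),
        reference=raw.reference.clip(lower=floor),
    )


def lowess_normalize(
    raw: RawIntensityData,
    span: float = 0.2,
    iterations: int = 3,
    min_finite: int = 30,
) -> ExpressionMatrix:
    """Per-array lowess normalisation of M on A.

    Returns M minus the lowess trend fitted through the (A, M) cloud of that
    array, so that the systematic intensity-dependent dye bias is removed while
    probe-level ratios are otherwise untouched.
    """
    s = raw.sample.to_numpy(dtype=float)
    r = raw.reference.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.log2(s) - np.log2(r)
        a = 0.5 * (np.log2(s) + np.log2(r))
    out = np.empty_like(m)
    for j in range(m.shape[1]):
        finite = np.isfinite(m[:, j]) & np.isfinite(a[:, j])
        if finite.sum() < min_finite:
            raise InsufficientDataError(
                f"array {raw.sample.columns[j]}: only {int(finite.sum())} finite (M, A) pairs"
            )
        fit = sm_lowess(
            m[finite, j],
            a[finite, j],
            frac=span,
            it=iterations,
            return_sorted=False,
        )
        col = np.full(m.shape[0], np.nan)
        col[finite] = m[finite, j] - fit
        out[:, j] = col
    values = pd.DataFrame(out, index=raw.sample.index, columns=raw.sample.columns)
    return ExpressionMatrix(values=values, samples=raw.design.samples.copy())


def log_ratios(raw: RawIntensityData) -> ExpressionMatrix:
    """Floored M-values (log2 sample/reference) without trend removal.

    Useful when no intensity-dependent bias is present (lowess is then the
    identity up to fit noise) and for MA diagnostics.
    """
    floored = floor_intensities(raw)
    m = np.log2(floored.sample.to_numpy()) - np.log2(floored.reference.to_numpy())
    values = pd.DataFrame(m, index=raw.sample.index, columns=raw.sample.columns)
    return ExpressionMatrix(values=values, samples=raw.design.samples.copy())


def filter_probes(
    flags: pd.DataFrame,
    design: ExperimentDesign | pd.DataFrame,
    fraction: float = 0.75,
    min_groups: int = 2,
) -> list[str]:
    """Probe-retention rule on detection flags.

    A probe is retained when, in at least ``min_groups`` experimental groups,
    it is flagged positive-and-significant on at least ``ceil(fraction * n_g)``
    of that group's arrays (group sizes taken after any array exclusions).
    """
    if not 0.0 < fraction <= 1.0:
        raise DimensionError("fraction must be in (0, 1]")
    if min_groups < 1:
        raise DimensionError("min_groups must be >= 1")
    samples = design.samples if isinstance(design, ExperimentDesign) else design
    if set(flags.columns) != set(samples["array_id"]):
        raise DimensionError("flag columns do not match the design's arrays")

    groups_ok = np.zeros(len(flags), dtype=int)
    for (_, _), grp in samples.groupby(["cross", "stage"]):
        arrays = list(grp["array_id"])
        need = math.ceil(fraction * len(arrays))
        counts = flags[arrays].to_numpy(dtype=bool).sum(axis=1)
        groups_ok += counts >= need
    retained = groups_ok >= min_groups
    return list(flags.index[retained])


def detect_outlier_arrays(expr: ExpressionMatrix, threshold_sd: float = 3.0) -> list[str]:
    """Flag arrays far from the centroid in the first two principal components.

    Distances are measured from the coordinate-wise median score and scaled by
    a robust SD (1.4826 * MAD) of the distances; arrays beyond
    ``threshold_sd`` robust SDs are flagged.  Flagging only — exclusion is a
    user decision.
    """
    x = expr.values.to_numpy(dtype=float).T  # arrays as observations
    if x.shape[0] < 3:
        raise InsufficientDataError("need >= 3 arrays for the outlier screen")
    centred = x - x.mean(axis=0)
    if not np.any(centred):
        return []
    scores = PCA(n_components=min(2, x.shape[0] - 1), svd_solver="full").fit_transform(x)
    centroid = np.median(scores, axis=0)
    dist = np.sqrt(((scores - centroid) ** 2).sum(axis=1))
    mad = np.median(np.abs(dist - np.median(dist)))
    scale = 1.4826 * mad
    if scale == 0.0 or not np.isfinite(threshold_sd):
        cut = np.inf if not np.isfinite(threshold_sd) else 0.0
        if cut == 0.0:
            # Degenerate spread: flag only arrays strictly away from the bulk.
            flagged = dist > np.median(dist)
        else:
            flagged = np.zeros(len(dist), dtype=bool)
    else:
        flagged = dist > threshold_sd * scale
    return [a for a, f in zip(expr.values.columns, flagged) if f]


def qc_report(
    flags: pd.DataFrame,
    retained: list[str],
    flagged_arrays: list[str],
) -> pd.DataFrame:
    """Tabular QC summary: per probe in/out, plus array flags as attrs."""
    kept = set(retained)
    report = pd.DataFrame(
        {
            "probe_id": flags.index,
            "retained": [p in kept for p in flags.index],
            "reason": ["" if p in kept else "detection_flag_rule" for p in flags.index],
        }
    )
    report.attrs["flagged_arrays"] = list(flagged_arrays)
    return report
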