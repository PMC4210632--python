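"""Synthetic two-channel microarray data with known ground truth.

Emulates a common-reference dual-label design comparing wild, hybrid
(domesticated dam x wild sire) and domesticated Atlantic salmon crosses at two
fry stages, six biological replicate arrays per group.  Every simulated data
set carries the full planted truth (group means, inheritance mode, pathway
membership, detection-flag failures) so each downstream stage of the pipeline
can be scored against what was actually planted.

Log2-scale generative model per probe and array::

    sample    = 2 ** (mu_group + b_gene,array + t_s + dye(A))
    reference = 2 ** (mu_pool  + t_r)

where ``b`` is the biological replicate deviate (shared by all probes of a
gene on one array), ``t_s``/``t_r`` are per-channel technical deviates and
``dye`` is an optional smooth intensity-dependent bias that the lowess
normalisation stage is expected to remove.  The reference pool is the
equal-weight mean of all six group means, mirroring an equimolar pool of every
experimental sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyInputError,
    InconsistentArchitectureError,
    InvalidDesignError,
)

CROSSES = ("wild", "hybrid", "domesticated")
STAGES = ("sac", "feeding")
MODES = ("additive", "maternal_dominant", "paternal_dominant", "overdominant")

#: Observed feeding-fry inheritance-mode mix (additive / maternal dominant /
#: paternal dominant / overdominant), used as the default planted mix.
FEEDING_FRY_MODE_MIX: Mapping[str, float] = {
    "additive": 0.45,
    "maternal_dominant": 0.422,
    "paternal_dominant": 0.061,
    "overdominant": 0.067,
}


@dataclass(frozen=True, eq=False)
class ExperimentDesign:
    """3 crosses x 2 stages x n replicate arrays, one group per array."""

    replicates: int
    samples: pd.DataFrame  # columns: array_id, cross, stage

    def __post_init__(self) -> None:
        if self.samples["array_id"].duplicated().any():
            raise InvalidDesignError("array ids must be unique")
        groups = set(zip(self.samples["cross"], self.samples["stage"]))
        expected = {(c, s) for c in CROSSES for s in STAGES}
        if groups != expected:
            raise InvalidDesignError(f"expected the 6 cross x stage groups, got {groups}")

    @property
    def array_ids(self) -> list[str]:
        return list(self.samples["array_id"])

    @property
    def groups(self) -> list[tuple[str, str]]:
        return [(c, s) for c in CROSSES for s in STAGES]

    def arrays_for(self, cross: str | None = None, stage: str | None = None) -> list[str]:
        m = pd.Series(True, index=self.samples.index)
        if cross is not None:
            m &= self.samples["cross"] == cross
        if stage is not None:
            m &= self.samples["stage"] == stage
        return list(self.samples.loc[m, "array_id"])


def build_design(replicates: int = 6, seed: int = 0) -> ExperimentDesign:
    """Lay out the full factorial design (6 groups x `replicates` arrays).

    The layout is deterministic; `seed` is accepted for interface symmetry
    with the stochastic generators and recorded nowhere else.
    """
    if replicates < 2:
        raise InvalidDesignError(f"need >= 2 replicates per group, got {replicates}")
    rows = [
        {"array_id": f"{cross}_{stage}_{r + 1}", "cross": cross, "stage": stage}
        for cross in CROSSES
        for stage in STAGES
        for r in range(replicates)
    ]
    return ExperimentDesign(replicates=replicates, samples=pd.DataFrame(rows))


@dataclass(frozen=True)
class TranscriptArchitecture:
    """Planted truth for one gene (optionally probed more than once).

    ``effect`` is the wild-minus-domesticated log2 offset; ``mode`` sets where
    the hybrid mean lies relative to the parental means.  ``effect == 0``
    marks a planted null.  For overdominant genes the hybrid is pushed outside
    the parental range by ``overdominance_shift`` log2 units on the
    ``overdominant_side`` ("maternal" = beyond the domesticated dam).
    """

    gene_id: str
    probe_ids: tuple[str, ...]
    baseline: float
    effect: float
    mode: str
    overdominance_shift: float = 0.0
    overdominant_side: str = "maternal"
    stage_specific: bool = False
    pathway_ids: frozenset[str] = field(default_factory=frozenset)
    annotated: bool = True

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise InconsistentArchitectureError(f"unknown mode {self.mode!r}")
        if not self.probe_ids:
            raise InconsistentArchitectureError(f"{self.gene_id}: needs >= 1 probe")
        if self.overdominant_side not in ("maternal", "paternal"):
            raise InconsistentArchitectureError(
                f"{self.gene_id}: bad overdominant_side {self.overdominant_side!r}"
            )


def plant_group_means(arch: TranscriptArchitecture) -> dict[str, tuple[float, float, float]]:
    """True per-stage (wild, hybrid, domesticated) log2 means for one gene.

    Inverts the inheritance statistic: with parental half-difference
    alpha = (W - D)/2 and dominance deviation delta = (W + D)/2 - H,

    * additive            -> H at the parental midpoint (delta = 0)
    * maternal_dominant   -> H = D (domesticated dam),  delta/alpha = +1
    * paternal_dominant   -> H = W (wild sire),         delta/alpha = -1
    * overdominant        -> H outside the parental range so |delta/alpha| > 1.5
    """
    out: dict[str, tuple[float, float, float]] = {}
    for stage in STAGES:
        effect = 0.0 if (arch.stage_specific and stage != "feeding") else arch.effect
        w = arch.baseline + effect / 2.0
        d = arch.baseline - effect / 2.0
        mid = arch.baseline
        if arch.mode == "additive":
            h = mid
        elif arch.mode == "maternal_dominant":
            h = d
        elif arch.mode == "paternal_dominant":
            h = w
        else:  # overdominant
            s = arch.overdominance_shift
            if effect == 0.0 and s == 0.0:
                raise InconsistentArchitectureError(
                    f"{arch.gene_id}: overdominant with zero effect and zero shift"
                )
            if effect != 0.0 and s <= abs(effect) / 4.0:
                # |delta/alpha| = 1 + s/|alpha| must exceed 1.5, i.e. s > |effect|/4
                raise InconsistentArchitectureError(
                    f"{arch.gene_id}: overdominance shift {s} too small for effect {effect}"
                )
            sign = 1.0 if effect >= 0 else -1.0
            if arch.overdominant_side == "maternal":
                h = d - sign * s  # beyond the domesticated dam
            else:
                h = w + sign * s  # beyond the wild sire
        out[stage] = (w, h, d)
    return out


@dataclass(frozen=True)
class NoiseModel:
    """Replicate-level and channel-level noise plus detection-flag failures.

    ``biological_sd`` is the per-replicate-array SD of a gene's deviation from
    its group mean (log2 units); ``technical_sd`` applies independently to each
    channel of each probe.  The resulting per-replicate SD of the log-ratio is
    sqrt(biological_sd**2 + 2 * technical_sd**2).  ``dye_bias`` is an optional
    smooth function of mean log-intensity A added to the sample channel.
    """

    biological_sd: float = 0.25
    technical_sd: float = 0.05
    flag_failure_rate: float = 0.05
    dye_bias: Callable[[np.ndarray], np.ndarray] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.biological_sd < 0 or self.technical_sd < 0:
            raise InvalidDesignError("noise SDs must be >= 0")
        if not 0.0 <= self.flag_failure_rate <= 1.0:
            raise InvalidDesignError("flag_failure_rate must be in [0, 1]")


@dataclass(frozen=True, eq=False)
class RawIntensityData:
    """Probe x array two-channel intensities, detection flags and truth."""

    sample: pd.DataFrame
    reference: pd.DataFrame
    flags: pd.DataFrame
    design: ExperimentDesign
    truth: tuple[TranscriptArchitecture, ...]

    def __post_init__(self) -> None:
        for other in (self.reference, self.flags):
            if other.shape != self.sample.shape:
                raise InvalidDesignError("channel/flag matrices must share one shape")


def true_group_mean_table(truth: Sequence[TranscriptArchitecture]) -> pd.DataFrame:
    """Planted per-gene W/H/D means, one row per gene, per-stage columns."""
    rows = []
    for arch in truth:
        means = plant_group_means(arch)
        row: dict[str, object] = {
            "gene_id": arch.gene_id,
            "mode": arch.mode,
            "effect": arch.effect,
            "annotated": arch.annotated,
            "n_probes": len(arch.probe_ids),
        }
        for stage, (w, h, d) in means.items():
            row[f"W_{stage}"] = w
            row[f"H_{stage}"] = h
            row[f"D_{stage}"] = d
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")


def simulate_intensities(
    design: ExperimentDesign,
    truth: Sequence[TranscriptArchitecture],
    noise: NoiseModel,
) -> RawIntensityData:
    """Draw two-channel intensities for every probe on every array."""
    if not truth:
        raise EmptyInputError("no transcript architectures supplied")

    probe_ids: list[str] = []
    gene_index: list[int] = []  # probe -> position in truth
    for gi, arch in enumerate(truth):
        for pid in arch.probe_ids:
            probe_ids.append(pid)
            gene_index.append(gi)
    gene_index_arr = np.asarray(gene_index)
    n_probes = len(probe_ids)

    arrays = design.samples
    n_arrays = len(arrays)
    group_of_array = list(zip(arrays["cross"], arrays["stage"]))

    # Planted log2 means: genes x 6 groups, expanded to probes x arrays.
    group_order = design.groups
    gene_means = np.empty((len(truth), len(group_order)))
    for gi, arch in enumerate(truth):
        means = plant_group_means(arch)
        for gj, (cross, stage) in enumerate(group_order):
            w, h, d = means[stage]
            gene_means[gi, gj] = {"wild": w, "hybrid": h, "domesticated": d}[cross]
    pool_gene = gene_means.mean(axis=1)

    col_group = np.asarray([group_order.index(g) for g in group_of_array])
    mu = gene_means[gene_index_arr][:, col_group]  # probes x arrays
    pool = pool_gene[gene_index_arr]

    rng = np.random.default_rng(noise.seed)
    bio_gene = rng.normal(0.0, noise.biological_sd, size=(len(truth), n_arrays))
    tech_s = rng.normal(0.0, noise.technical_sd, size=(n_probes, n_arrays))
    tech_r = rng.normal(0.0, noise.technical_sd, size=(n_probes, n_arrays))
    flag_draws = rng.random(size=(n_probes, n_arrays))

    log2_sample = mu + bio_gene[gene_index_arr] + tech_s
    log2_ref = pool[:, None] + tech_r
    if noise.dye_bias is not None:
        a0 = 0.5 * (mu + pool[:, None])  # noiseless mean log-intensity
        log2_sample = log2_sample + noise.dye_bias(a0)

    sample = np.clip(np.exp2(log2_sample), 0.0, None)
    reference = np.clip(np.exp2(log2_ref), 0.0, None)
    flags = flag_draws >= noise.flag_failure_rate

    cols = list(arrays["array_id"])
    return RawIntensityData(
        sample=pd.DataFrame(sample, index=probe_ids, columns=cols),
        reference=pd.DataFrame(reference, index=probe_ids, columns=cols),
        flags=pd.DataFrame(flags, index=probe_ids, columns=cols),
        design=design,
        truth=tuple(truth),
    )


def _normalised_mix(mode_proportions: Mapping[str, float]) -> tuple[list[str], np.ndarray]:
    modes = list(mode_proportions)
    bad = set(modes) - set(MODES)
    if bad:
        raise InvalidDesignError(f"unknown modes in mix: {sorted(bad)}")
    p = np.asarray([mode_proportions[m] for m in modes], dtype=float)
    if (p < 0).any() or p.sum() <= 0:
        raise InvalidDesignError("mode proportions must be nonnegative and sum > 0")
    return modes, p / p.sum()


def make_architectures(
    n_genes: int,
    *,
    mode_proportions: Mapping[str, float] = FEEDING_FRY_MODE_MIX,
    effect_size: float = 1.0,
    overdominance_shift: float | None = None,
    maternal_overdominant_fraction: float = 0.5,
    null_fraction: float = 0.0,
    duplicate_probe_fraction: float = 0.0,
    annotated_fraction: float = 1.0,
    stage_specific_fraction: float = 0.0,
    baseline_mean: float = 8.0,
    baseline_sd: float = 1.5,
    seed: int = 0,
) -> list[TranscriptArchitecture]:
    """Draw a gene panel with planted inheritance modes.

    Non-null genes receive a wild-vs-domesticated offset of ``effect_size``
    log2 units with random sign and a mode drawn from ``mode_proportions``.
    ``null_fraction`` of genes get effect 0 (planted nulls, additive).
    ``duplicate_probe_fraction`` of genes are probed twice (both probes share
    the gene's true means).  Overdominant genes sit ``overdominance_shift``
    (default: ``effect_size``, i.e. delta/alpha = +-3) beyond a parent, on the
    maternal side with probability ``maternal_overdominant_fraction``.
    """
    if n_genes < 1:
        raise EmptyInputError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    modes, probs = _normalised_mix(mode_proportions)
    shift = effect_size if overdominance_shift is None else overdominance_shift

    drawn_modes = rng.choice(len(modes), size=n_genes, p=probs)
    is_null = rng.random(n_genes) < null_fraction
    signs = rng.choice([-1.0, 1.0], size=n_genes)
    baselines = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    duplicated = rng.random(n_genes) < duplicate_probe_fraction
    annotated = rng.random(n_genes) < annotated_fraction
    stage_spec = rng.random(n_genes) < stage_specific_fraction
    maternal_side = rng.random(n_genes) < maternal_overdominant_fraction

    out = []
    width = len(str(n_genes))
    for i in range(n_genes):
        gene = f"g{i + 1:0{width}d}"
        n_probes = 2 if duplicated[i] else 1
        probe_ids = tuple(f"{gene}_p{k + 1}" for k in range(n_probes))
        mode = "additive" if is_null[i] else modes[drawn_modes[i]]
        effect = 0.0 if is_null[i] else signs[i] * effect_size
        out.append(
            TranscriptArchitecture(
                gene_id=gene,
                probe_ids=probe_ids,
                baseline=float(baselines[i]),
                effect=float(effect),
                mode=mode,
                overdominance_shift=shift if mode == "overdominant" else 0.0,
                overdominant_side="maternal" if maternal_side[i] else "paternal",
                stage_specific=bool(stage_spec[i]),
                annotated=bool(annotated[i]),
            )
        )
    return out


def make_pathway_scenario(
    n_genes: int = 2000,
    n_sets: int = 200,
    set_size: int = 25,
    *,
    effect_size: float = 1.0,
    direction: str = "up",
    seed: int = 0,
) -> tuple[list[TranscriptArchitecture], dict[str, list[str]]]:
    """One coordinated perturbed pathway among null pathways.

    The first set's genes all move ``effect_size`` log2 units in ``direction``
    (wild is the control, so "up" means higher in the domesticated cross);
    the remaining ``n_sets - 1`` sets are drawn from unperturbed background
    genes.  Returns (architectures, {set_id: [gene ids]}).
    """
    if n_sets < 1 or set_size * n_sets > n_genes * n_sets:  # defensive
        raise InvalidDesignError("bad pathway scenario shape")
    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    genes = [f"g{i + 1:0{width}d}" for i in range(n_genes)]
    planted = list(rng.choice(n_genes, size=set_size, replace=False))
    background = [i for i in range(n_genes) if i not in set(planted)]

    sets: dict[str, list[str]] = {"set001": [genes[i] for i in planted]}
    for s in range(1, n_sets):
        members = rng.choice(len(background), size=set_size, replace=False)
        sets[f"set{s + 1:03d}"] = [genes[background[i]] for i in members]

    sign = -1.0 if direction == "down" else 1.0
    planted_set = set(planted)
    baselines = rng.normal(8.0, 1.5, size=n_genes)
    archs = []
    for i, gene in enumerate(genes):
        # "up" = up in domesticated vs wild control => effect (W - D) negative
        effect = -sign * effect_size if i in planted_set else 0.0
        archs.append(
            TranscriptArchitecture(
                gene_id=gene,
                probe_ids=(f"{gene}_p1",),
                baseline=float(baselines[i]),
                effect=effect,
                mode="additive",
                pathway_ids=frozenset(
                    sid for sid, members in sets.items() if gene in members
                ),
            )
        )
    return archs, sets
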