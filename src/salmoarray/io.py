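"""Text-table and GMT input/output plus run configuration.

All interchange is plain TSV for inspectability; gene sets use the de facto
standard GMT dialect (set name TAB description TAB gene ids).
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .enrichment import GeneSet
from .errors import ParseError, ValidationError
from .simulate import (
    ExperimentDesign,
    RawIntensityData,
    TranscriptArchitecture,
    true_group_mean_table,
)


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Read a probe/gene x array TSV matrix (first column = row ids)."""
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    if table.empty and len(table.columns) == 0:
        raise ParseError(f"{path}: no data columns")
    dup = table.index[table.index.duplicated()]
    if len(dup):
        raise ParseError(f"{path}: duplicate row id {dup[0]!r}")
    bad = table.columns[[not pd.api.types.is_numeric_dtype(t) for t in table.dtypes]]
    if len(bad):
        col = bad[0]
        row = int(np.argmax(pd.to_numeric(table[col], errors="coerce").isna())) + 2
        raise ParseError(f"{path}: non-numeric value in column {col!r} near line {row}")
    return table


def write_table(table: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=index)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file; description may carry 'functional_group|free text'."""
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                warnings.warn(f"{path}:{lineno}: blank line skipped")
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            set_id, description = parts[0], parts[1]
            genes: list[str] = []
            seen: set[str] = set()
            for g in parts[2:]:
                if not g:
                    continue
                if g in seen:
                    warnings.warn(f"{path}:{lineno}: duplicate gene {g!r} in set {set_id!r}")
                    continue
                seen.add(g)
                genes.append(g)
            group = description.split("|", 1)[0] if "|" in description else ""
            sets.append(GeneSet(set_id=set_id, name=description, functional_group=group, genes=tuple(genes)))
    return sets


def write_gmt(sets: Sequence[GeneSet] | Mapping[str, Iterable[str]], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if isinstance(sets, Mapping):
            for sid, genes in sets.items():
                fh.write("\t".join([sid, sid, *genes]) + "\n")
        else:
            for gs in sets:
                desc = f"{gs.functional_group}|{gs.name}" if gs.functional_group else gs.name
                fh.write("\t".join([gs.set_id, desc or gs.set_id, *gs.genes]) + "\n")


def write_simulation(raw: RawIntensityData, outdir: str | Path) -> None:
    """Emit the simulator's standard TSVs (+ pathways.gmt when planted)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    long = pd.DataFrame(
        {
            "probe_id": np.repeat(raw.sample.index, raw.sample.shape[1]),
            "array_id": np.tile(raw.sample.columns, raw.sample.shape[0]),
            "sample": raw.sample.to_numpy().ravel(),
            "reference": raw.reference.to_numpy().ravel(),
            "flag": raw.flags.to_numpy().ravel().astype(int),
        }
    )
    long.to_csv(outdir / "intensities.tsv", sep="\t", index=False)
    raw.design.samples.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    truth = true_group_mean_table(raw.truth)
    truth.to_csv(outdir / "truth.tsv", sep="\t")
    pathways: dict[str, list[str]] = {}
    for arch in raw.truth:
        for sid in sorted(arch.pathway_ids):
            pathways.setdefault(sid, []).append(arch.gene_id)
    if pathways:
        write_gmt(pathways, outdir / "pathways.gmt")


def read_simulation(indir: str | Path) -> RawIntensityData:
    """Rebuild a RawIntensityData from the simulator TSV dialect."""
    indir = Path(indir)
    long = pd.read_csv(indir / "intensities.tsv", sep="\t")
    needed = {"probe_id", "array_id", "sample", "reference", "flag"}
    if not needed <= set(long.columns):
        raise ParseError(f"{indir / 'intensities.tsv'}: missing columns {needed - set(long.columns)}")
    samples = pd.read_csv(indir / "samples.tsv", sep="\t")
    probe_order = long["probe_id"].drop_duplicates()
    sample = long.pivot(index="probe_id", columns="array_id", values="sample")
    reference = long.pivot(index="probe_id", columns="array_id", values="reference")
    flags = long.pivot(index="probe_id", columns="array_id", values="flag").astype(bool)
    order = list(samples["array_id"])
    replicates = int(samples.groupby(["cross", "stage"]).size().min())
    design = ExperimentDesign(replicates=replicates, samples=samples)
    probes = list(probe_order)
    return RawIntensityData(
        sample=sample.loc[probes, order],
        reference=reference.loc[probes, order],
        flags=flags.loc[probes, order],
        design=design,
        truth=(),
    )


def annotation_from_truth(truth: Sequence[TranscriptArchitecture]) -> pd.DataFrame:
    """probe_id -> gene_id annotation table implied by the planted truth."""
    rows = [
        {"probe_id": pid, "gene_id": arch.gene_id, "annotated": arch.annotated}
        for arch in truth
        for pid in arch.probe_ids
    ]
    return pd.DataFrame(rows)


@dataclass
class RunConfig:
    """All stage parameters with their conventional defaults."""

    replicates: int = 6
    n_genes: int = 2000
    seed: int = 0
    biological_sd: float = 0.25
    technical_sd: float = 0.05
    flag_failure_rate: float = 0.05
    effect_size: float = 1.0
    null_fraction: float = 0.5
    retain_fraction: float = 0.75
    min_groups: int = 2
    lowess_span: float = 0.2
    lowess_iterations: int = 3
    outlier_sd: float = 3.0
    p_strict: float = 0.01
    fc_strict: float = 1.3
    p_lenient: float = 0.05
    anova_fdr: float = 0.10
    set_q: float = 0.1
    min_set_size: int = 10
    exclude_group: str = "Human Diseases"
    plot_limit: float = 5.0

    def __post_init__(self) -> None:
        checks = [
            (self.replicates >= 2, "replicates must be >= 2"),
            (self.n_genes >= 1, "n_genes must be >= 1"),
            (self.biological_sd >= 0, "biological_sd must be >= 0"),
            (self.technical_sd >= 0, "technical_sd must be >= 0"),
            (0 <= self.flag_failure_rate <= 1, "flag_failure_rate must be in [0, 1]"),
            (0 < self.retain_fraction <= 1, "retain_fraction must be in (0, 1]"),
            (self.min_groups >= 1, "min_groups must be >= 1"),
            (0 < self.lowess_span <= 1, "lowess_span must be in (0, 1]"),
            (self.fc_strict >= 1, "fc_strict must be >= 1"),
            (0 < self.p_strict <= 1, "p_strict must be in (0, 1]"),
            (0 < self.p_lenient <= 1, "p_lenient must be in (0, 1]"),
            (0 < self.anova_fdr <= 1, "anova_fdr must be in (0, 1]"),
            (0 < self.set_q <= 1, "set_q must be in (0, 1]"),
            (self.min_set_size >= 1, "min_set_size must be >= 1"),
            (self.plot_limit > 0, "plot_limit must be > 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValidationError(msg)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)
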