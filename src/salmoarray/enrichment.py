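"""Directional gene-set perturbation testing and heat-map ordering.

A GAGE-style re-implementation (not a clone): for every treat/control array
pair a per-gene log2 change column is formed ("unpaired one-on-one"
scheme), each column is tested with a two-sample Welch t of the set's genes
against the background genes (one-tailed for up/down, on absolute changes for
two-way perturbation), and per-column p-values are combined with a Stouffer
sum whose variance accounts for the overlap between pair columns that share
an array (columns sharing one array have correlation 1/2, so an
independence Stouffer would be anticonservative).  BH correction is applied
across sets within each direction.

Also provides redundancy grouping of significant sets, extraction of
"essential" genes (set members moving beyond one SD of all genes' mean
changes) and Pearson-distance average-linkage clustering for heat-map row
ordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .errors import EmptyInputError, InsufficientDataError, InvalidDesignError
from .diffexpr import _welch_arrays, dedupe_unique_genes
from .qc import ExpressionMatrix

logger = logging.getLogger(__name__)

DIRECTIONS = ("up", "down", "two_way")


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (e.g. a KEGG pathway) with a functional group label."""

    set_id: str
    name: str = ""
    functional_group: str = ""
    genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.genes:
            raise EmptyInputError(f"gene set {self.set_id!r} is empty")


def as_gene_sets(sets: Mapping[str, Iterable[str]] | Sequence[GeneSet]) -> list[GeneSet]:
    if isinstance(sets, Mapping):
        return [GeneSet(set_id=k, name=k, genes=tuple(v)) for k, v in sets.items()]
    return list(sets)


def per_gene_contrast_stats(
    expr: ExpressionMatrix,
    stage: str,
    treat: str = "domesticated",
    control: str = "wild",
    annotation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-gene log2 changes for every treat/control array pair of a stage.

    With ``annotation`` (probe_id -> gene_id, annotated flag) probes are
    collapsed to genes by keeping each gene's most significant probe under a
    treat-vs-control Welch t-test; otherwise probe ids are used as gene ids.
    Columns are labelled "<treat array>|<control array>".
    """
    cols_t = expr.arrays_for(cross=treat, stage=stage)
    cols_c = expr.arrays_for(cross=control, stage=stage)
    if not cols_t or not cols_c:
        raise InvalidDesignError(f"stage {stage!r}: missing group for contrast")
    t = expr.values[cols_t].to_numpy(dtype=float)
    c = expr.values[cols_c].to_numpy(dtype=float)
    contrasts = (t[:, :, None] - c[:, None, :]).reshape(t.shape[0], -1)
    names = [f"{ta}|{ca}" for ta in cols_t for ca in cols_c]
    table = pd.DataFrame(contrasts, index=expr.values.index, columns=names)
    if annotation is not None:
        _, p = _welch_arrays(t, c)
        probe_p = pd.DataFrame({"probe_id": expr.values.index, "p_value": p})
        unique = dedupe_unique_genes(probe_p, annotation)
        table = table.loc[unique["probe_id"]]
        table.index = pd.Index(unique["gene_id"], name="gene_id")
    return table


def _pair_effective_columns(columns: Sequence[str]) -> float:
    """Effective variance of the Stouffer sum for one-on-one pair columns.

    Pair columns sharing exactly one array have correlation 1/2; for the full
    nt x nc grid the variance of the summed z-scores is
    K * (1 + ((nt - 1) + (nc - 1)) / 2) with K = nt * nc.  Falls back to K
    (independence) when columns do not parse as "treat|control".
    """
    k = len(columns)
    try:
        treats, controls = zip(*(c.split("|", 1) for c in columns))
    except ValueError:
        return float(k)
    nt, nc = len(set(treats)), len(set(controls))
    if nt * nc != k:
        return float(k)
    return k * (1.0 + 0.5 * ((nt - 1) + (nc - 1)))


def gage_set_test(
    contrasts: pd.DataFrame,
    sets: Mapping[str, Iterable[str]] | Sequence[GeneSet],
    direction: str = "up",
    min_size: int = 10,
    q_cut: float = 0.1,
    exclude_groups: Iterable[str] = (),
) -> pd.DataFrame:
    """Directional gene-set perturbation test against the gene background.

    Per pair column, a two-sample Welch t compares the set genes' changes
    with all other genes' changes (one-tailed: "up" = greater, "down" =
    smaller; "two_way" tests absolute changes, one-tailed greater).  Column
    p-values are Stouffer-combined with a design-based variance correction
    and sets receive BH q-values within the direction.  Sets with fewer than
    ``min_size`` measured genes are skipped with a log record, as are sets
    whose functional group is listed in ``exclude_groups``.
    """
    if direction not in DIRECTIONS:
        raise InvalidDesignError(f"unknown direction {direction!r}")
    gene_sets = as_gene_sets(sets)
    excluded = set(exclude_groups)
    measured = pd.Index(contrasts.index)
    x = contrasts.to_numpy(dtype=float)
    if direction == "two_way":
        x = np.abs(x)
    n_genes, n_cols = x.shape

    kept: list[GeneSet] = []
    sizes: list[int] = []
    rows_mask: list[np.ndarray] = []
    pos = {g: i for i, g in enumerate(measured)}
    for gs in gene_sets:
        if gs.functional_group in excluded:
            logger.info("set %s skipped: functional group %r excluded", gs.set_id, gs.functional_group)
            continue
        idx = [pos[g] for g in set(gs.genes) if g in pos]
        if len(idx) < min_size:
            logger.info("set %s skipped: %d measured genes < min_size %d", gs.set_id, len(idx), min_size)
            continue
        mask = np.zeros(n_genes, dtype=bool)
        mask[idx] = True
        kept.append(gs)
        sizes.append(len(idx))
        rows_mask.append(mask)
    if not kept:
        return pd.DataFrame(
            columns=["set_id", "name", "functional_group", "direction", "p_value", "bh_q", "set_size", "significant"]
        )

    m = np.stack(rows_mask)  # sets x genes
    n_set = m.sum(axis=1).astype(float)[:, None]
    tot_sum = x.sum(axis=0)[None, :]
    tot_sumsq = (x**2).sum(axis=0)[None, :]
    set_sum = m @ x
    set_sumsq = m @ (x**2)
    comp_n = float(n_genes) - n_set
    set_mean = set_sum / n_set
    comp_mean = (tot_sum - set_sum) / comp_n
    set_var = (set_sumsq - n_set * set_mean**2) / (n_set - 1.0)
    comp_var = (tot_sumsq - set_sumsq - comp_n * comp_mean**2) / (comp_n - 1.0)
    set_var = np.clip(set_var, 0.0, None)
    comp_var = np.clip(comp_var, 0.0, None)

    with np.errstate(divide="ignore", invalid="ignore"):
        se2 = set_var / n_set + comp_var / comp_n
        t = (set_mean - comp_mean) / np.sqrt(se2)
        df = se2**2 / (
            (set_var / n_set) ** 2 / (n_set - 1.0) + (comp_var / comp_n) ** 2 / (comp_n - 1.0)
        )
    df = np.where(np.isfinite(df) & (df > 0), df, 1.0)
    t = np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=-np.inf)
    if direction == "down":
        p_col = stats.t.cdf(t, df)
    else:
        p_col = stats.t.sf(t, df)
    p_col = np.clip(p_col, 1e-300, 1.0 - 1e-16)
    z = stats.norm.isf(p_col)
    var_eff = _pair_effective_columns(list(contrasts.columns))
    z_comb = z.sum(axis=1) / np.sqrt(var_eff)
    p = stats.norm.sf(z_comb)

    _, q, _, _ = multipletests(p, method="fdr_bh")
    out = pd.DataFrame(
        {
            "set_id": [gs.set_id for gs in kept],
            "name": [gs.name for gs in kept],
            "functional_group": [gs.functional_group for gs in kept],
            "direction": direction,
            "p_value": p,
            "bh_q": q,
            "set_size": sizes,
            "significant": q <= q_cut,
        }
    )
    return out.sort_values(["p_value", "set_id"], kind="mergesort").reset_index(drop=True)


def gage_all_directions(
    contrasts: pd.DataFrame,
    sets,
    min_size: int = 10,
    q_cut: float = 0.1,
    exclude_groups: Iterable[str] = (),
) -> pd.DataFrame:
    """Run the set test for up, down and two-way perturbation."""
    parts = [
        gage_set_test(contrasts, sets, direction=d, min_size=min_size, q_cut=q_cut, exclude_groups=exclude_groups)
        for d in DIRECTIONS
    ]
    return pd.concat(parts, ignore_index=True)


def nonredundant_sets(
    results: pd.DataFrame,
    sets: Mapping[str, Iterable[str]] | Sequence[GeneSet],
    measured_genes: Iterable[str] | None = None,
    overlap_fraction: float = 0.5,
) -> pd.DataFrame:
    """Group significant sets sharing most of their core genes.

    Two significant sets merge when the smaller set shares at least
    ``overlap_fraction`` of its core (measured) genes with the other; merging
    is transitive (connected components).  Each group's representative is its
    smallest-p member.
    """
    gene_sets = {gs.set_id: gs for gs in as_gene_sets(sets)}
    sig = results[results["significant"]].copy()
    if sig.empty:
        return pd.DataFrame(columns=["set_id", "group", "representative", "p_value"])
    universe = set(measured_genes) if measured_genes is not None else None
    cores: dict[str, set[str]] = {}
    for sid in sig["set_id"]:
        core = set(gene_sets[sid].genes)
        if universe is not None:
            core &= universe
        cores[sid] = core

    ids = list(sig["set_id"])
    parent = {s: s for s in ids}

    def find(s: str) -> str:
        while parent[s] != s:
            parent[s] = parent[parent[s]]
            s = parent[s]
        return s

    for i, si in enumerate(ids):
        for sj in ids[i + 1 :]:
            a, b = cores[si], cores[sj]
            smaller = min(len(a), len(b))
            if smaller and len(a & b) >= overlap_fraction * smaller:
                parent[find(si)] = find(sj)

    sig["group"] = [find(s) for s in sig["set_id"]]
    best = sig.sort_values(["p_value", "set_id"], kind="mergesort").drop_duplicates("group")
    reps = set(best["set_id"])
    sig["representative"] = sig["set_id"].isin(reps)
    return sig[["set_id", "group", "representative", "p_value"]].reset_index(drop=True)


def essential_genes(
    contrasts: pd.DataFrame,
    significant_sets: Mapping[str, Iterable[str]] | Sequence[GeneSet] | Iterable[str],
    sets: Mapping[str, Iterable[str]] | Sequence[GeneSet] | None = None,
) -> pd.DataFrame:
    """Members of significant sets changing beyond one SD of all genes.

    A gene is kept when it belongs to at least one significant set and its
    mean change across pair columns lies more than one SD (of all genes'
    mean changes) away from the grand mean.
    """
    if sets is not None:
        lookup = {gs.set_id: gs for gs in as_gene_sets(sets)}
        members: set[str] = set()
        for sid in significant_sets:
            members |= set(lookup[sid].genes)
    else:
        members = set()
        for gs in as_gene_sets(significant_sets):  # type: ignore[arg-type]
            members |= set(gs.genes)
    mean_change = contrasts.mean(axis=1)
    grand = float(mean_change.mean())
    sd = float(mean_change.std(ddof=1))
    keep = mean_change.index.isin(members) & (np.abs(mean_change - grand) > sd)
    return pd.DataFrame(
        {"gene_id": mean_change.index[keep], "mean_change": mean_change[keep].to_numpy()}
    ).reset_index(drop=True)


def cluster_genes(rows: pd.DataFrame) -> tuple[list[str], np.ndarray, list[str]]:
    """Average-linkage clustering on Pearson-correlation distance (1 - r).

    Returns (leaf-ordered gene ids, linkage matrix, genes excluded for zero
    variance).  Ordering is deterministic; scipy's linkage breaks distance
    ties by the lower original observation index.
    """
    variances = rows.var(axis=1, ddof=0)
    excluded = list(rows.index[variances == 0.0])
    usable = rows[variances > 0.0]
    if len(usable) < 2:
        raise InsufficientDataError("need >= 2 genes with nonzero variance to cluster")
    corr = np.corrcoef(usable.to_numpy(dtype=float))
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = hierarchy.leaves_list(z)
    return [usable.index[i] for i in order], z, excluded
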