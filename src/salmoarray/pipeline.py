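"""End-to-end orchestration: simulate -> qc -> de -> enrich -> inherit.

Every stage logs how many probes/genes/sets survive each filter, and a run
manifest records package version, seeds and every configuration value so a
run can be reproduced exactly.
"""

from __future__ import annotations

import logging
from contextlib import contextmanager
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import diffexpr, enrichment, inheritance, qc
from .errors import SalmoArrayError
from .io import (
    RunConfig,
    annotation_from_truth,
    write_gmt,
    write_simulation,
    write_table,
)
from .simulate import (
    STAGES,
    NoiseModel,
    RawIntensityData,
    build_design,
    make_architectures,
    simulate_intensities,
)

logger = logging.getLogger(__name__)


@contextmanager
def _stage(name: str):
    logger.info("stage %s: start", name)
    try:
        yield
    except SalmoArrayError as exc:
        raise type(exc)(f"stage {name}: {exc}") from exc
    logger.info("stage %s: done", name)


def simulate_from_config(config: RunConfig) -> RawIntensityData:
    design = build_design(config.replicates)
    truth = make_architectures(
        config.n_genes,
        effect_size=config.effect_size,
        null_fraction=config.null_fraction,
        duplicate_probe_fraction=0.2,
        seed=config.seed,
    )
    noise = NoiseModel(
        biological_sd=config.biological_sd,
        technical_sd=config.technical_sd,
        flag_failure_rate=config.flag_failure_rate,
        seed=config.seed + 1,
    )
    return simulate_intensities(design, truth, noise)


def run_qc(raw: RawIntensityData, config: RunConfig) -> tuple[qc.ExpressionMatrix, pd.DataFrame]:
    floored = qc.floor_intensities(raw)
    expr = qc.lowess_normalize(floored, span=config.lowess_span, iterations=config.lowess_iterations)
    retained = qc.filter_probes(raw.flags, raw.design, config.retain_fraction, config.min_groups)
    logger.info("probe filter: %d of %d probes retained", len(retained), len(raw.flags))
    expr = expr.subset_probes(retained)
    flagged = qc.detect_outlier_arrays(expr, config.outlier_sd)
    if flagged:
        logger.info("outlier screen flagged arrays: %s", flagged)
    report = qc.qc_report(raw.flags, retained, flagged)
    return expr, report


def chunked_gene_sets(gene_ids, set_size: int = 20) -> dict[str, list[str]]:
    """Deterministic synthetic pathway grouping used by the demo pipeline."""
    genes = sorted(set(gene_ids))
    return {
        f"pathway{(i // set_size) + 1:03d}": genes[i : i + set_size]
        for i in range(0, len(genes) - set_size + 1, set_size)
    }


def run_all(config: RunConfig, outdir: str | Path) -> dict:
    """Run the full pipeline into `outdir`; returns summary counts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {}

    with _stage("simulate"):
        raw = simulate_from_config(config)
        write_simulation(raw, outdir / "simulation")
        annotation = annotation_from_truth(raw.truth)
        summary["n_probes"] = len(raw.sample)
        summary["n_arrays"] = raw.sample.shape[1]

    with _stage("qc"):
        expr, report = run_qc(raw, config)
        write_table(expr.values, outdir / "expression.tsv")
        write_table(report, outdir / "qc_report.tsv", index=False)
        summary["n_retained_probes"] = len(expr.values)

    gene_sets = chunked_gene_sets(annotation.loc[annotation["annotated"], "gene_id"])
    write_gmt(gene_sets, outdir / "gene_sets.gmt")

    for stage in STAGES:
        with _stage(f"de[{stage}]"):
            de = diffexpr.pairwise_de(
                expr, stage, p_strict=config.p_strict, fc_strict=config.fc_strict, p_lenient=config.p_lenient
            )
            strict_lists = {}
            for comp, table in de.items():
                write_table(table, outdir / f"de_{stage}_{comp}.tsv", index=False)
                strict_lists[comp] = set(table.loc[table["passes_strict"], "probe_id"])
                logger.info(
                    "%s %s: %d strict, %d lenient of %d probes",
                    stage, comp, int(table["passes_strict"].sum()), int(table["passes_lenient"].sum()), len(table),
                )
            regions = diffexpr.venn_partition(strict_lists)
            venn = pd.DataFrame(
                {"region": ["&".join(k) for k in regions], "size": [len(v) for v in regions.values()]}
            )
            write_table(venn, outdir / f"venn_{stage}.tsv", index=False)
            summary[f"strict_de_{stage}"] = {k: len(v) for k, v in strict_lists.items()}

        with _stage(f"anova[{stage}]"):
            anova = diffexpr.welch_anova(expr, stage)
            anova["bh_q"], anova["significant"] = diffexpr.bh_fdr(anova["p_value"], config.anova_fdr)
            unique = diffexpr.dedupe_unique_genes(anova, annotation)
            write_table(unique, outdir / f"anova_{stage}.tsv", index=False)
            sig = unique[unique["significant"]]
            logger.info("%s: %d unique annotated genes, %d at FDR %.2f", stage, len(unique), len(sig), config.anova_fdr)
            summary[f"anova_significant_{stage}"] = len(sig)

        with _stage(f"enrich[{stage}]"):
            contrasts = enrichment.per_gene_contrast_stats(expr, stage, annotation=annotation)
            results = enrichment.gage_all_directions(
                contrasts,
                gene_sets,
                min_size=config.min_set_size,
                q_cut=config.set_q,
                exclude_groups=(config.exclude_group,),
            )
            write_table(results, outdir / f"set_results_{stage}.tsv", index=False)
            sig_sets = results[results["significant"]]
            summary[f"significant_sets_{stage}"] = len(sig_sets)
            if not sig_sets.empty:
                groups = enrichment.nonredundant_sets(results, gene_sets, measured_genes=contrasts.index)
                write_table(groups, outdir / f"nonredundant_sets_{stage}.tsv", index=False)
                ess = enrichment.essential_genes(
                    contrasts, sig_sets["set_id"].unique(), enrichment.as_gene_sets(gene_sets)
                )
                write_table(ess, outdir / f"essential_genes_{stage}.tsv", index=False)
                if len(ess) >= 2:
                    order, _, dropped = enrichment.cluster_genes(
                        contrasts.loc[contrasts.index.intersection(ess["gene_id"])]
                    )
                    write_table(pd.DataFrame({"gene_id": order}), outdir / f"cluster_order_{stage}.tsv", index=False)
                    if dropped:
                        logger.info("%s: %d zero-variance genes excluded from clustering", stage, len(dropped))

        with _stage(f"inherit[{stage}]"):
            sig = unique[unique["significant"]]
            if sig.empty:
                logger.info("%s: no ANOVA-significant genes; inheritance skipped", stage)
                continue
            rec = inheritance.export_scatter_table(
                expr, stage, list(sig["probe_id"]), plot_limit=config.plot_limit
            )
            rec["gene_id"] = list(sig["gene_id"])
            write_table(rec, outdir / f"inheritance_{stage}.tsv", index=False)
            props = inheritance.summarize_proportions(rec)
            write_table(props, outdir / f"proportions_{stage}.tsv", index=False)
            summary[f"inheritance_genes_{stage}"] = len(rec)

    manifest = {"package_version": __version__, "config": config.to_dict(), "summary": summary}
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return summary
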