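"""End-to-end orchestration: simulate -> gates -> nomination -> validation.

`run_all` executes every stage on a synthetic bundle and writes one output
table per stage. With a fixed config (seed included) the written tables are
byte-identical across runs.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .config import PipelineConfig, RunLog
from .containers import ExpressionMatrix, GeneSet, irs_frame
from .diagnostics import DiagnosticCurve, diagnostic_curve
from .diffomics import deg_one_vs_rest, dep_knockdown_concordance
from .methylome import MethylationReport, methylation_separation, select_gene_cpgs
from .nominate import (CandidateReport, attach_provenance, intersect_candidates,
                       prioritize)
from .regulatory import (SuperEnhancerCall, assign_peaks_to_genes,
                         call_super_enhancers, stitch_peaks)
from .signatures import (EnrichmentResult, anchor_correlation_signature,
                         kd_combined_signature, preranked_gsea, score_correlation,
                         ssgsea_matrix)
from .synthdata import SyntheticBundle, TruthParams, generate_multiomics, write_bundle

__all__ = ["run_all", "RunResult", "score_single_cells"]

_FLOAT_FMT = "%.10g"


def score_single_cells(counts: pd.DataFrame, gene_sets: list[GeneSet],
                       alpha: float = 0.25,
                       min_genes_detected: int = 200) -> pd.DataFrame:
    """ssGSEA on log1p-transformed single-cell counts.

    Cells with fewer than ``min_genes_detected`` nonzero genes are dropped
    (basic QC; the threshold is config-exposed at the call site).
    """
    detected = (counts > 0).sum(axis=0)
    keep = detected[detected >= min_genes_detected].index
    if keep.empty:
        raise ValueError("no cell passes the detected-genes threshold")
    log_counts = np.log1p(counts[keep])
    return ssgsea_matrix(log_counts, gene_sets, alpha=alpha)


@dataclass
class RunResult:
    bundle: SyntheticBundle
    deg_table: pd.DataFrame
    deg_passing: set[str]
    dep_tables: dict[str, pd.DataFrame]
    dep_concordant: set[str]
    peak_assignments: dict[str, list[tuple[str, int]]]
    fusion_target_genes: set[str]
    se_call: SuperEnhancerCall
    report: CandidateReport
    priority: pd.DataFrame
    anchor_set: GeneSet
    kd_set: GeneSet
    bulk_scores: pd.DataFrame
    score_corr: pd.DataFrame
    gsea: EnrichmentResult
    sc_scores: pd.DataFrame
    methylation: MethylationReport
    curve: DiagnosticCurve
    log: RunLog


def run_all(config: PipelineConfig | None = None,
            outdir: str | Path | None = None,
            params: TruthParams | None = None) -> RunResult:
    """Run the complete pipeline on a freshly generated synthetic bundle."""
    cfg = config or PipelineConfig()
    log = RunLog(seed=cfg.random_seed)
    t = cfg.thresholds

    bundle = generate_multiomics(params, seed=cfg.random_seed)
    target = bundle.params.target_entity
    log.append("simulate", {"genes": bundle.params.n_genes,
                            "samples": len(bundle.expression.sample_ids)},
               inputs=cfg.to_dict())

    deg_table, deg_passing = deg_one_vs_rest(
        bundle.expression, target, lfc_gate=t.deg_lfc, padj_gate=t.deg_padj)
    log.append("deg", {"passing": len(deg_passing)})

    dep_tables, dep_concordant = dep_knockdown_concordance(
        bundle.kd_tables, lfc_gate=t.dep_lfc, padj_gate=t.dep_padj)
    log.append("dep", {"concordant": len(dep_concordant)})

    assignments = assign_peaks_to_genes(bundle.peaks, bundle.genes,
                                        cfg.max_tss_distance)
    fusion_targets = set(assignments)
    log.append("annotate_peaks", {"target_genes": len(fusion_targets)})

    stitched = stitch_peaks(bundle.h3k27ac, cfg.stitching_distance,
                            tss_exclusion=cfg.tss_exclusion,
                            genes=bundle.genes if cfg.tss_exclusion else None)
    se_call = call_super_enhancers(stitched)
    log.append("se_call", {"stitched": len(stitched),
                           "super": se_call.n_super})

    report = intersect_candidates(deg_passing, fusion_targets, dep_concordant)
    if not report.candidates:
        raise RuntimeError("triple intersection is empty: no candidate "
                           "biomarkers on this bundle")
    attach_provenance(report, deg_table, dep_tables, assignments)
    priority = prioritize(report.candidates, bundle.expression, target)
    log.append("nominate", {"candidates": len(report.candidates)})

    anchor = str(priority["candidate"].iloc[0])
    anchor_set = anchor_correlation_signature(bundle.expression, anchor,
                                              target, top_n=100)
    kd_set = kd_combined_signature(list(dep_tables.values()),
                                   padj_gate=t.dep_padj,
                                   name="fusion_activated")
    log.append("signature", {"anchor_members": len(anchor_set),
                             "kd_members": len(kd_set)})

    bulk_scores = ssgsea_matrix(bundle.expression, [anchor_set, kd_set],
                                alpha=cfg.ssgsea_alpha)
    corr = score_correlation(bulk_scores)
    log.append("ssgsea", {"signatures": len(bulk_scores)})

    ranked = deg_table.set_index("feature")["log2fc"]
    gsea = preranked_gsea(ranked, anchor_set,
                          n_permutations=cfg.gsea_permutations,
                          seed=cfg.random_seed % (2 ** 31))
    log.append("gsea", {"members": gsea.n_members})

    sc_scores = score_single_cells(bundle.sc_counts, [anchor_set, kd_set],
                                   alpha=cfg.ssgsea_alpha)
    log.append("sc_score", {"cells": sc_scores.shape[1]})

    anchor_row = bundle.genes.df.set_index("gene_id").loc[anchor]
    anchor_row = anchor_row.copy()
    anchor_row["gene_id"] = anchor
    cpgs = select_gene_cpgs(bundle.methylation, anchor_row, flank_bp=1500)
    meth_report = methylation_separation(bundle.methylation, cpgs, target)
    log.append("methyl", {"cpgs": len(cpgs)})

    curve = diagnostic_curve(bundle.irs_records, target)
    log.append("irs_curve", {"records": len(bundle.irs_records)})

    result = RunResult(
        bundle=bundle, deg_table=deg_table, deg_passing=deg_passing,
        dep_tables=dep_tables, dep_concordant=dep_concordant,
        peak_assignments=assignments, fusion_target_genes=fusion_targets,
        se_call=se_call, report=report, priority=priority,
        anchor_set=anchor_set, kd_set=kd_set, bulk_scores=bulk_scores,
        score_corr=corr, gsea=gsea, sc_scores=sc_scores,
        methylation=meth_report, curve=curve, log=log)
    if outdir is not None:
        _write_outputs(result, cfg, Path(outdir))
    return result


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False,
               index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index=index,
              index_label=index_label)


def _write_outputs(r: RunResult, cfg: PipelineConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    write_bundle(r.bundle, out / "bundle")
    _write_tsv(r.deg_table, out / "deg.tsv")
    for line, table in r.dep_tables.items():
        _write_tsv(table, out / f"dep_{line}.tsv")
    rows = [(g, name, d) for g, lst in sorted(r.peak_assignments.items())
            for name, d in lst]
    _write_tsv(pd.DataFrame(rows, columns=["gene", "peak", "distance_bp"]),
               out / "gene_peaks.tsv")
    _write_tsv(r.se_call.table, out / "se_table.tsv")
    (out / "se_cutoff.txt").write_text(
        f"cutoff_signal\t{r.se_call.cutoff_signal:.10g}\n"
        f"cutoff_rank\t{r.se_call.cutoff_index}\n"
        f"n_super\t{r.se_call.n_super}\n"
        f"weak_elbow\t{r.se_call.weak_elbow}\n")
    _write_tsv(r.report.provenance, out / "candidates.tsv")
    _write_tsv(r.priority, out / "priority.tsv")
    mio.write_gmt([r.anchor_set, r.kd_set], out / "signatures.gmt")
    _write_tsv(r.bulk_scores, out / "ssgsea_scores.tsv", index=True,
               index_label="signature")
    _write_tsv(r.score_corr, out / "score_correlation.tsv", index=True,
               index_label="signature")
    _write_tsv(pd.DataFrame([{
        "set": r.anchor_set.name, "es": r.gsea.es, "nes": r.gsea.nes,
        "pvalue": r.gsea.pvalue, "padj": r.gsea.padj,
        "nperm": r.gsea.n_permutations, "seed": r.gsea.seed,
    }]), out / "gsea.tsv")
    _write_tsv(r.sc_scores, out / "sc_scores.tsv", index=True,
               index_label="signature")
    _write_tsv(r.methylation.embedding, out / "methyl_embedding.tsv",
               index=True, index_label="sample")
    _write_tsv(pd.DataFrame([{
        "silhouette": r.methylation.silhouette,
        "statistic": r.methylation.statistic,
        "pvalue": r.methylation.pvalue,
        "direction": r.methylation.direction,
        "mean_beta_target": r.methylation.mean_beta_target,
        "mean_beta_rest": r.methylation.mean_beta_rest,
    }]), out / "methyl_report.tsv")
    _write_tsv(r.curve.table, out / "irs_curve.tsv")
    _write_tsv(pd.DataFrame([{
        "specificity_at_irs_gt1": r.curve.specificity_at_positive_rule,
        "sensitivity_at_irs_gt1": r.curve.sensitivity_at_positive_rule,
        "max_cutoff_full_sensitivity": r.curve.max_cutoff_full_sensitivity,
    }]), out / "operating_points.tsv")
    r.log.write(out / "run_log.txt")
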