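"""Candidate nomination: triple intersection and prioritization.

The biomarker shortlist is the intersection of three independent gates —
genes overexpressed in the target entity, genes with a fusion-factor peak
near their TSS, and proteins concordantly regulated upon fusion knockdown
(mapped to genes). Candidates are then ranked by expression level in the
target entity with pairwise rank-sum comparisons.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .diffomics import rank_sum_test

__all__ = ["intersect_candidates", "prioritize", "CandidateReport"]

logger = logging.getLogger(__name__)


@dataclass
class CandidateReport:
    """Intersection members with per-gate provenance."""

    candidates: list[str]                       # lexicographic
    provenance: pd.DataFrame = field(default_factory=pd.DataFrame)
    dropped_proteins: list[str] = field(default_factory=list)


def intersect_candidates(deg_genes: set[str], target_genes: set[str],
                         dep_proteins: set[str],
                         protein_gene_map: dict[str, str] | None = None,
                         ) -> CandidateReport:
    """Intersect the three nomination gates.

    ``protein_gene_map`` maps each protein id to at most one gene id
    (identity mapping when omitted); unmappable proteins are dropped with a
    warning. Candidate order is lexicographic, hence deterministic.
    """
    dropped: list[str] = []
    if protein_gene_map is None:
        dep_genes = set(dep_proteins)
    else:
        dep_genes = set()
        for prot in dep_proteins:
            gene = protein_gene_map.get(prot)
            if gene is None:
                dropped.append(prot)
            else:
                dep_genes.add(gene)
        if dropped:
            logger.warning("dropped %d unmappable protein(s): %s",
                           len(dropped), sorted(dropped)[:10])
    candidates = sorted(set(deg_genes) & set(target_genes) & dep_genes)
    return CandidateReport(candidates=candidates,
                           dropped_proteins=sorted(dropped))


def attach_provenance(report: CandidateReport, deg_table: pd.DataFrame,
                      dep_tables: dict[str, pd.DataFrame],
                      peak_assignments: dict[str, list[tuple[str, int]]],
                      gene_protein_map: dict[str, str] | None = None,
                      ) -> CandidateReport:
    """Fill the per-candidate provenance columns of a report in place.

    Columns: DEG log2fc/padj, per-line DEP log2fc/padj, and the distance of
    the nearest assigned peak.
    """
    rows = []
    deg = deg_table.set_index("feature")
    for gene in report.candidates:
        prot = gene if gene_protein_map is None else gene_protein_map[gene]
        row: dict[str, object] = {
            "candidate": gene,
            "deg_log2fc": float(deg.loc[gene, "log2fc"]),
            "deg_padj": float(deg.loc[gene, "padj"]),
            "nearest_peak_bp": int(min(d for _, d in peak_assignments[gene])),
        }
        for line, table in dep_tables.items():
            t = table.set_index("feature")
            row[f"dep_log2fc_{line}"] = float(t.loc[prot, "log2fc"])
            row[f"dep_padj_{line}"] = float(t.loc[prot, "padj"])
        rows.append(row)
    report.provenance = pd.DataFrame(rows)
    return report


def prioritize(candidates: list[str], expr: ExpressionMatrix,
               target_entity: str) -> pd.DataFrame:
    """Rank candidates by median target-entity expression, descending.

    Ties break lexicographically. For every adjacent pair in the ranking a
    two-sided rank-sum p on their per-sample expression values within the
    target entity is reported (``pairwise_p_vs_next``; NaN for the last row).
    """
    if not candidates:
        raise ValueError("no candidates to prioritize")
    missing = [c for c in candidates if c not in expr.feature_ids]
    if missing:
        raise KeyError(f"candidates absent from expression matrix: {missing}")
    samples = expr.samples_of(target_entity)
    sub = expr.values.loc[candidates, samples]
    medians = sub.median(axis=1)
    ranked = sorted(candidates, key=lambda g: (-medians[g], g))
    pvals: list[float] = []
    for gene, nxt in zip(ranked, ranked[1:]):
        a, b = sub.loc[gene].to_numpy(), sub.loc[nxt].to_numpy()
        pvals.append(1.0 if np.array_equal(a, b) else rank_sum_test(a, b)[1])
    pvals.append(np.nan)
    return pd.DataFrame({
        "candidate": ranked,
        "rank": np.arange(1, len(ranked) + 1),
        "median_expression": [float(medians[g]) for g in ranked],
        "pairwise_p_vs_next": pvals,
    })
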