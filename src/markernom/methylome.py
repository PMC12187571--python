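"""Methylation analysis around a locus of interest.

Selects CpGs in a gene-plus-flank window, embeds the samples on the first
two principal components of the beta submatrix, quantifies how well the
target entity separates from the mimics (silhouette), and tests per-sample
mean beta for hypomethylation with a two-sided rank-sum test.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .containers import GeneAnnotation, MethylationMatrix
from .diffomics import rank_sum_test

__all__ = ["select_gene_cpgs", "methylation_separation", "MethylationReport"]


def select_gene_cpgs(meth: MethylationMatrix, gene_row: pd.Series,
                     flank_bp: int = 1500) -> list[str]:
    """CpG ids within [gene start - flank, gene end + flank), position-sorted.

    ``gene_row`` is one row of a :class:`GeneAnnotation` frame (needs
    ``chrom``, ``start``, ``end``).
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    lo = int(gene_row["start"]) - flank_bp
    hi = int(gene_row["end"]) + flank_bp
    c = meth.coords
    hit = c[(c["chrom"] == gene_row["chrom"])
            & (c["position"] >= lo) & (c["position"] < hi)]
    hit = hit.sort_values("position", kind="mergesort")
    cpgs = [cid for cid in hit["cpg_id"] if cid in meth.beta.index]
    if not cpgs:
        raise ValueError(
            f"no CpGs within {flank_bp} bp of {gene_row['gene_id']}; "
            "try a larger flank")
    return cpgs


@dataclass
class MethylationReport:
    embedding: pd.DataFrame        # samples x (PC1, PC2)
    silhouette: float              # target vs rest on the 2-D embedding
    statistic: float               # rank-sum U of per-sample mean beta
    pvalue: float
    direction: str                 # 'target_lower' | 'target_higher'
    mean_beta_target: float
    mean_beta_rest: float


def methylation_separation(meth: MethylationMatrix, cpg_ids: list[str],
                           target_entity: str) -> MethylationReport:
    """Embed, score and test the target entity on a CpG subset.

    PCA (2 components) on the centered beta submatrix gives the embedding;
    the silhouette of target-vs-rest on those coordinates quantifies the
    visual clustering; the hypomethylation call is a two-sided rank-sum test
    on per-sample mean beta with the direction reported.
    """
    if len(cpg_ids) < 2:
        raise ValueError("need >= 2 CpGs")
    sub = meth.beta.loc[cpg_ids]
    labels = meth.entity_labels
    is_target = (labels == target_entity).to_numpy()
    if is_target.sum() < 3 or (~is_target).sum() < 3:
        raise ValueError("need >= 3 samples in target and rest groups")
    x = sub.to_numpy().T                           # samples x cpgs
    if np.allclose(x, x[0]):
        raise ValueError("constant beta submatrix")
    coords = PCA(n_components=2, svd_solver="full").fit_transform(
        x - x.mean(axis=0))
    embedding = pd.DataFrame(coords, index=sub.columns, columns=["PC1", "PC2"])
    sil = float(silhouette_score(coords, is_target))
    mean_beta = x.mean(axis=1)
    u, p = rank_sum_test(mean_beta[is_target], mean_beta[~is_target])
    mt, mr = float(mean_beta[is_target].mean()), float(mean_beta[~is_target].mean())
    return MethylationReport(
        embedding=embedding,
        silhouette=sil,
        statistic=u,
        pvalue=p,
        direction="target_lower" if mt < mr else "target_higher",
        mean_beta_target=mt,
        mean_beta_rest=mr,
    )
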