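"""Regulatory genomics: peak-to-gene assignment and super-enhancer calling.

Peak assignment links fusion-factor binding peaks to candidate target genes
by distance to the strand-aware TSS. Super-enhancer calling follows the
ROSE recipe: stitch nearby enhancer peaks, rank stitched regions by total
signal, and cut the rank-signal curve at the tangent-slope-1 point of the
scaled hockey-stick.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GeneAnnotation, PeakSet

__all__ = [
    "assign_peaks_to_genes",
    "stitch_peaks",
    "call_super_enhancers",
    "SuperEnhancerCall",
]

logger = logging.getLogger(__name__)


def assign_peaks_to_genes(peaks: PeakSet, genes: GeneAnnotation,
                          max_tss_distance: int = 100_000,
                          ) -> dict[str, list[tuple[str, int]]]:
    """Assign each peak to every gene whose TSS lies within reach.

    The distance is measured from the TSS to the nearest peak edge and is 0
    when the TSS falls inside the peak. A peak may serve several genes and a
    gene may collect several peaks. Peaks on chromosomes absent from the
    annotation are skipped with a warning.

    Returns
    -------
    dict
        gene_id -> list of (peak name, distance bp), distance-sorted.
        Genes with at least one peak form the candidate fusion-target set.
    """
    if max_tss_distance <= 0:
        raise ValueError("max_tss_distance must be > 0")
    out: dict[str, list[tuple[str, int]]] = {}
    gene_df = genes.df
    known_chroms = set(gene_df["chrom"])
    for chrom, chrom_peaks in peaks.df.groupby("chrom", sort=True):
        if chrom not in known_chroms:
            logger.warning("skipping %d peak(s) on %s: chromosome absent "
                           "from gene annotation", len(chrom_peaks), chrom)
            continue
        cg = gene_df[gene_df["chrom"] == chrom]
        tss = cg["tss"].to_numpy()[:, None]                     # genes x 1
        start = chrom_peaks["start"].to_numpy()[None, :]        # 1 x peaks
        end = chrom_peaks["end"].to_numpy()[None, :]
        # distance from TSS to nearest edge (left edge = start, right edge =
        # exclusive end); 0 inside the half-open interval
        dist = np.maximum.reduce([start - tss, tss - end,
                                  np.zeros_like(start - tss)])
        gi, pi = np.nonzero(dist <= max_tss_distance)
        names = chrom_peaks["name"].to_numpy()
        gids = cg["gene_id"].to_numpy()
        for g, p in zip(gi, pi):
            out.setdefault(gids[g], []).append((names[p], int(dist[g, p])))
    for gene in out:
        out[gene].sort(key=lambda t: (t[1], t[0]))
    return out


def stitch_peaks(peaks: PeakSet, stitching_distance: int = 12_500,
                 tss_exclusion: int = 0,
                 genes: GeneAnnotation | None = None) -> pd.DataFrame:
    """Transitively merge same-chromosome peaks with gaps <= the distance.

    Overlapping peaks always merge (gap <= 0). Total signal is the sum of
    member peak scores; the member count is carried along. With
    ``tss_exclusion`` > 0 and a gene annotation, peaks fully contained in a
    TSS +/- exclusion window are dropped before stitching (ROSE's optional
    promoter exclusion).

    Returns
    -------
    DataFrame
        columns: region_id, chrom, start, end, n_peaks, total_signal;
        intervals pairwise disjoint per chromosome, coordinate-sorted.
    """
    if stitching_distance < 0:
        raise ValueError("stitching_distance must be >= 0")
    df = peaks.sorted().df
    if tss_exclusion > 0:
        if genes is None:
            raise ValueError("tss_exclusion requires a gene annotation")
        keep = np.ones(len(df), dtype=bool)
        for chrom, cg in genes.df.groupby("chrom"):
            mask = df["chrom"].to_numpy() == chrom
            if not mask.any():
                continue
            s = df["start"].to_numpy()[mask][:, None]
            e = df["end"].to_numpy()[mask][:, None]
            tss = cg["tss"].to_numpy()[None, :]
            contained = ((s >= tss - tss_exclusion)
                         & (e <= tss + tss_exclusion)).any(axis=1)
            keep[np.nonzero(mask)[0][contained]] = False
        df = df[keep]

    rows = []
    for chrom, cp in df.groupby("chrom", sort=True):
        starts = cp["start"].to_numpy()
        ends = cp["end"].to_numpy()
        scores = cp["score"].to_numpy()
        i = 0
        while i < len(cp):
            s, e, sig, n = starts[i], ends[i], scores[i], 1
            j = i + 1
            while j < len(cp) and starts[j] - e <= stitching_distance:
                e = max(e, ends[j])
                sig += scores[j]
                n += 1
                j += 1
            rows.append((chrom, int(s), int(e), n, float(sig)))
            i = j
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_peaks",
                                      "total_signal"])
    out.insert(0, "region_id",
               [f"{c}:{s}-{e}" for c, s, e in
                zip(out["chrom"], out["start"], out["end"])])
    return out


@dataclass
class SuperEnhancerCall:
    """Ranked stitched regions with the tangent cutoff annotation."""

    table: pd.DataFrame          # + rank, is_super columns, ascending signal
    cutoff_signal: float
    cutoff_index: int            # 1-based rank of the cutoff region
    n_super: int
    weak_elbow: bool             # max(x - y) < 0.1: no pronounced hockey stick


def call_super_enhancers(stitched: pd.DataFrame,
                         weak_elbow_margin: float = 0.1) -> SuperEnhancerCall:
    """Call super-enhancers by the scaled rank-signal tangent cutoff.

    Regions are sorted ascending by total signal; with rank scaled to
    x_i = i/n and signal to y_i = s_i / s_max, the cutoff sits at
    i* = argmax_i (x_i - y_i) — the tangent-slope-1 point of a convex
    hockey-stick curve — with ties broken toward the larger i. Regions with
    total signal strictly above s_{i*} are super-enhancers.

    A near-linear curve (max(x - y) < ``weak_elbow_margin``) still yields a
    cutoff but is flagged ``weak_elbow``.
    """
    if len(stitched) < 2:
        raise ValueError("need >= 2 stitched regions to place a cutoff")
    table = stitched.sort_values(
        ["total_signal", "region_id"], kind="mergesort").reset_index(drop=True)
    s = table["total_signal"].to_numpy(dtype=float)
    if np.allclose(s, s[0]):
        raise ValueError("degenerate signal vector, no cutoff")
    n = len(s)
    x = np.arange(1, n + 1) / n
    y = s / s.max()
    gap = x - y
    istar = int(np.flatnonzero(gap == gap.max())[-1])     # ties -> larger i
    cutoff = float(s[istar])
    table["rank"] = np.arange(1, n + 1)
    table["is_super"] = s > cutoff
    return SuperEnhancerCall(
        table=table,
        cutoff_signal=cutoff,
        cutoff_index=istar + 1,
        n_super=int(table["is_super"].sum()),
        weak_elbow=bool(gap.max() < weak_elbow_margin),
    )
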