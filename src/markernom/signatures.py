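"""Gene signatures and enrichment scoring.

Two signature constructors (anchor-gene correlation within one entity;
concordant regulation across knockdown experiments), single-sample GSEA
scoring, a permutation-null preranked GSEA, and signature-score
correlation.

ssGSEA here is the rank-weighted running-difference form: genes are ranked
by expression per sample, member genes carry weight ``rank^alpha`` (midranks
for ties, the top gene holding the largest rank), and the enrichment score
is the *sum* over the ranked list of the weighted in-set ECDF minus the
out-of-set ECDF. With ``alpha = 0`` the score depends on ranks only and is
invariant under any strictly monotone transform of the values.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, GeneSet

__all__ = [
    "anchor_correlation_signature",
    "kd_combined_signature",
    "ssgsea_score",
    "ssgsea_matrix",
    "preranked_gsea",
    "score_correlation",
    "EnrichmentResult",
]


# --------------------------------------------------------------------------
# signature construction
# --------------------------------------------------------------------------

def anchor_correlation_signature(expr: ExpressionMatrix, anchor_gene: str,
                                 target_entity: str, top_n: int = 100,
                                 min_r: float | None = None) -> GeneSet:
    """Genes most Pearson-correlated with an anchor gene within one entity.

    Correlations are computed across the target entity's samples only; the
    anchor itself is excluded from the members. Members are the ``top_n``
    genes by r, intersected with ``{r >= min_r}`` when ``min_r`` is given.
    """
    if anchor_gene not in expr.feature_ids:
        raise KeyError(f"anchor gene {anchor_gene!r} absent from matrix")
    if top_n < 1 and min_r is None:
        raise ValueError("need top_n >= 1 or min_r")
    samples = expr.samples_of(target_entity)
    if len(samples) < 3:
        raise ValueError("need >= 3 target-entity samples for correlation")
    sub = expr.values[samples]
    anchor = sub.loc[anchor_gene].to_numpy()
    if np.allclose(anchor, anchor[0]):
        raise ValueError("anchor gene has zero variance in the target entity")
    x = sub.to_numpy()
    xc = x - x.mean(axis=1, keepdims=True)
    ac = anchor - anchor.mean()
    denom = np.sqrt((xc ** 2).sum(axis=1) * (ac ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, xc @ ac / denom, np.nan)
    corr = pd.Series(r, index=expr.feature_ids).drop(anchor_gene).dropna()
    corr = corr.sort_values(ascending=False, kind="mergesort")
    members = corr.head(top_n)
    if min_r is not None:
        members = members[members >= min_r]
    if members.empty:
        raise ValueError("no genes satisfy the correlation criteria")
    return GeneSet(name=f"{anchor_gene}_correlated",
                   members=list(members.index),
                   description=f"top Pearson-correlated genes with "
                               f"{anchor_gene} in {target_entity}")


def kd_combined_signature(diff_tables: list[pd.DataFrame],
                          padj_gate: float = 0.01, min_support: int | None = None,
                          direction: str = "down",
                          name: str = "kd_signature") -> GeneSet:
    """Signature of genes concordantly regulated upon knockdown.

    A gene enters the fusion-activated set when padj < ``padj_gate`` and
    log2FC < 0 (down upon knockdown) in at least ``min_support`` of the
    supplied differential tables (default: all of them). ``direction='up'``
    yields the symmetric fusion-repressed set.
    """
    if len(diff_tables) < 2:
        raise ValueError("need >= 2 differential tables")
    if min_support is None:
        min_support = len(diff_tables)
    if min_support == 0:
        raise ValueError("min_support must be >= 1")
    if min_support > len(diff_tables):
        raise ValueError("min_support exceeds number of tables")
    if direction not in ("down", "up"):
        raise ValueError("direction must be 'down' or 'up'")
    support: pd.Series | None = None
    for table in diff_tables:
        t = table.set_index("feature")
        sig = t["padj"] < padj_gate
        sig &= (t["log2fc"] < 0) if direction == "down" else (t["log2fc"] > 0)
        support = sig.astype(int) if support is None else support.add(
            sig.astype(int), fill_value=0)
    assert support is not None
    members = sorted(support.index[support >= min_support])
    if not members:
        raise ValueError("no gene satisfies the support rule")
    return GeneSet(name=name, members=members, direction=direction,
                   description=f"padj<{padj_gate} & {direction}-regulated in "
                               f">={min_support} knockdown experiments")


# --------------------------------------------------------------------------
# ssGSEA
# --------------------------------------------------------------------------

def _rank_weights(values: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """Descending order (stable, value then position) and midrank weights.

    Returns (order, weights_in_original_index): weight_g = midrank_g^alpha
    where midranks are ascending so the highest value carries weight ~N.
    """
    n = values.size
    order = np.lexsort((np.arange(n), -values))
    midranks = stats.rankdata(values)           # ascending midranks, ties averaged
    return order, midranks ** alpha


def ssgsea_score(sample_values: pd.Series, gene_set: GeneSet,
                 alpha: float = 0.25) -> float:
    """Single-sample enrichment score of one gene set in one sample.

    ES = sum_i [P_in(i) - P_out(i)] over the descending-ranked gene list,
    with P_in the weighted ECDF of member genes (weights rank^alpha) and
    P_out the unweighted ECDF of non-members.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    universe = sample_values.index
    member_mask = universe.isin(gene_set.members)
    k = int(member_mask.sum())
    n = len(universe)
    if k == 0:
        raise ValueError(f"gene set {gene_set.name!r} does not intersect the "
                         "measured universe")
    if k == n:
        raise ValueError(f"gene set {gene_set.name!r} covers the whole "
                         "universe; the out-of-set ECDF is undefined")
    values = sample_values.to_numpy(dtype=float)
    order, weights = _rank_weights(values, alpha)
    in_set = member_mask[order]
    w = np.where(in_set, weights[order], 0.0)
    w_total = w.sum()
    if w_total == 0:                             # all member weights zero
        w = in_set.astype(float)
        w_total = float(k)
    p_in = np.cumsum(w) / w_total
    p_out = np.cumsum(~in_set) / (n - k)
    return float(np.sum(p_in - p_out))


def ssgsea_matrix(expr: pd.DataFrame | ExpressionMatrix,
                  gene_sets: list[GeneSet], alpha: float = 0.25,
                  normalize: bool = False) -> pd.DataFrame:
    """Score every gene set in every sample (signatures x samples).

    With ``normalize``, all scores are divided by the global score range
    (max - min across the whole matrix).
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    scores = np.empty((len(gene_sets), values.shape[1]))
    for j, sample in enumerate(values.columns):
        col = values[sample]
        for i, gs in enumerate(gene_sets):
            try:
                scores[i, j] = ssgsea_score(col, gs, alpha=alpha)
            except ValueError as exc:
                raise ValueError(f"sample {sample!r}: {exc}") from exc
    out = pd.DataFrame(scores, index=[gs.name for gs in gene_sets],
                       columns=values.columns)
    if normalize:
        span = float(out.to_numpy().max() - out.to_numpy().min())
        if span > 0:
            out = out / span
    return out


# --------------------------------------------------------------------------
# preranked GSEA
# --------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    """Preranked enrichment of one gene set against a ranked statistic."""

    es: float
    nes: float
    pvalue: float
    n_permutations: int
    seed: int
    n_members: int
    padj: float | None = None        # filled when several sets are tested
    degenerate_null: bool = False    # no same-sign permutation ES observed

    def __post_init__(self) -> None:
        if self.es * self.nes < 0:
            raise ValueError("NES must carry the sign of ES")


def _running_es(pos: np.ndarray, w: np.ndarray, n: int) -> float:
    """Signed maximal deviation of the GSEA running sum.

    ``pos``: ascending 1-based positions of the members in the ranked list;
    ``w``: matching member increments (need not be normalized). Between
    member positions the walk decreases linearly, so its extremes occur
    right after a member (maximum candidates) or right before one (minimum
    candidates, plus the terminal 0).
    """
    k = pos.size
    w_total = w.sum()
    if w_total <= 0:
        w = np.ones(k)
        w_total = float(k)
    cum_in = np.cumsum(w) / w_total
    miss = n - k
    dec_at = (pos - np.arange(1, k + 1)) / miss
    cand_max = cum_in - dec_at
    cum_before = np.concatenate(([0.0], cum_in[:-1]))
    dec_before = (pos - 1 - np.arange(k)) / miss
    cand_min = cum_before - dec_before
    es_pos = float(cand_max.max())
    es_neg = float(min(cand_min.min(), 0.0))
    return es_pos if es_pos >= -es_neg else es_neg


def preranked_gsea(ranked_stats: pd.Series, gene_set: GeneSet,
                   n_permutations: int = 1000, seed: int = 0,
                   weight_p: float = 1.0) -> EnrichmentResult:
    """Preranked GSEA with a seeded gene-sampling permutation null.

    The running sum increments by ``|stat|^weight_p`` (normalized to total
    1 over members) at member genes and decrements by ``1/(N-|S|)`` at
    non-members; ES is the signed maximal deviation. The null re-draws
    ``n_permutations`` random gene sets of the same size; NES divides ES by
    the mean |null ES| of matching sign and the p-value is
    ``(1 + #{null >=|<= ES, matching sign}) / (1 + #matching-sign nulls)``.
    """
    import warnings
    if not np.isfinite(ranked_stats.to_numpy()).all():
        raise ValueError("ranked statistics must be finite")
    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations: p-values are coarse",
                      stacklevel=2)
    n = len(ranked_stats)
    member_mask = ranked_stats.index.isin(gene_set.members)
    k = int(member_mask.sum())
    if not (1 <= k < n):
        raise ValueError("gene set must hit the universe without covering it")

    stat = ranked_stats.to_numpy(dtype=float)
    order = np.lexsort((np.arange(n), -stat))    # descending, stable
    incr = np.abs(stat[order]) ** weight_p
    in_set = member_mask[order]
    pos_obs = np.flatnonzero(in_set) + 1
    es = _running_es(pos_obs, incr[pos_obs - 1], n)

    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        pos = np.sort(rng.choice(n, size=k, replace=False)) + 1
        null[i] = _running_es(pos, incr[pos - 1], n)

    same_sign = null >= 0 if es >= 0 else null < 0
    n_same = int(same_sign.sum())
    degenerate = n_same == 0
    if degenerate:
        nes = 0.0 if es == 0 else np.sign(es) * np.inf
        nes = float(np.nan_to_num(nes, posinf=np.inf, neginf=-np.inf))
        pvalue = 1.0 / (n_permutations + 1)
    else:
        mean_mag = float(np.abs(null[same_sign]).mean())
        nes = es / mean_mag if mean_mag > 0 else 0.0
        extreme = (null[same_sign] >= es if es >= 0 else null[same_sign] <= es)
        pvalue = (1 + int(extreme.sum())) / (1 + n_same)
    return EnrichmentResult(es=es, nes=float(nes), pvalue=float(pvalue),
                            n_permutations=n_permutations, seed=seed,
                            n_members=k, degenerate_null=degenerate)


# --------------------------------------------------------------------------
# score correlation
# --------------------------------------------------------------------------

def score_correlation(scores: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation of signature score rows.

    Zero-variance rows yield missing entries (off-diagonal NaN) with a
    warning; the diagonal is 1 by convention.
    """
    import warnings
    if scores.shape[1] < 3:
        raise ValueError("need >= 3 samples to correlate signature scores")
    x = scores.to_numpy(dtype=float)
    sd = x.std(axis=1)
    if (sd == 0).any():
        flat = list(scores.index[sd == 0])
        warnings.warn(f"zero-variance signature rows: {flat}; correlations "
                      "reported as missing", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=scores.index, columns=scores.index)
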