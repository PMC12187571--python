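"""Differential omics gates: one-vs-rest expression and knockdown proteomics.

The transcriptomic gate compares the target entity against the pooled rest
with a two-sided Mann-Whitney test per gene; the proteomic gate requires
significant, same-sign regulation upon fusion knockdown in every cell line
(Welch t at replicate level). Both gates adjust p-values per analysis with
Benjamini-Hochberg.
"""
from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix

__all__ = [
    "rank_sum_test",
    "benjamini_hochberg",
    "deg_one_vs_rest",
    "dep_knockdown_concordance",
]

_EXACT_MAX_N = 8


def rank_sum_test(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney rank-sum test.

    Returns ``(U_a, p)`` where ``U_a`` is the Mann-Whitney statistic of
    ``group_a``. Ties are handled by midranks. When both groups have at most
    8 observations the p-value comes from exact enumeration of all
    label assignments (two-sided as twice the smaller tail, capped at 1);
    otherwise from the tie-corrected normal approximation with continuity
    correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    if n1 <= _EXACT_MAX_N and n2 <= _EXACT_MAX_N:
        return _exact_rank_sum(a, b)
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def _exact_rank_sum(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided p by enumerating all C(n1+n2, n1) group assignments.

    Midranks make the enumeration valid in the presence of ties (the exact
    null distribution of U is then conditional on the observed tie pattern).
    """
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)              # midranks
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    total = comb(n1 + n2, n1)
    n_le = 0
    n_ge = 0
    offset = n1 * (n1 + 1) / 2.0
    tol = 1e-9
    for idx in combinations(range(n1 + n2), n1):
        u = ranks[list(idx)].sum() - offset
        if u <= u_obs + tol:
            n_le += 1
        if u >= u_obs - tol:
            n_ge += 1
    p = min(1.0, 2.0 * min(n_le, n_ge) / total)
    return float(u_obs), float(p)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment.

    padj_i = min_{j >= rank(i)} m * p_(j) / j, capped at 1, returned in the
    original order. All p must lie in (0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _diff_table(features, log2fc, pvalue, padj, lfc_gate, padj_gate,
                two_sided_lfc: bool) -> pd.DataFrame:
    lfc_ok = np.abs(log2fc) > lfc_gate if two_sided_lfc else log2fc > lfc_gate
    return pd.DataFrame({
        "feature": features,
        "log2fc": log2fc,
        "pvalue": pvalue,
        "padj": padj,
        "direction": np.where(log2fc < 0, "down", "up"),
        "pass": lfc_ok & (padj < padj_gate),
    })


def _vectorized_mwu(target: np.ndarray, rest: np.ndarray) -> np.ndarray:
    """Per-row two-sided Mann-Whitney p, tie-corrected normal approximation."""
    res = stats.mannwhitneyu(target, rest, axis=1, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return np.asarray(res.pvalue, dtype=float)


def deg_one_vs_rest(expr: ExpressionMatrix, target_entity: str,
                    lfc_gate: float = 2.5, padj_gate: float = 0.01,
                    per_entity: bool = False,
                    ) -> tuple[pd.DataFrame, set[str]]:
    """One-vs-rest differential expression for one tumor entity.

    Per gene: log2FC = mean(target) - mean(pooled rest); p from the two-sided
    rank-sum test of target vs pooled rest; BH adjustment across all genes.
    A gene passes when log2FC > ``lfc_gate`` and padj < ``padj_gate``.

    Parameters
    ----------
    per_entity
        Strict mode: additionally require mean(target) - mean(entity) >
        ``lfc_gate`` against *every* non-target entity separately, not just
        the pool.

    Returns
    -------
    (table, passing)
        The per-gene differential table and the set of passing gene ids.
    """
    target_samples = expr.samples_of(target_entity)
    if len(target_samples) < 3:
        raise ValueError(
            f"target entity {target_entity!r} needs >= 3 samples")
    rest_samples = [s for s in expr.sample_ids if s not in set(target_samples)]
    if not rest_samples:
        raise ValueError("no non-target samples")

    tvals = expr.values[target_samples].to_numpy()
    rvals = expr.values[rest_samples].to_numpy()
    log2fc = tvals.mean(axis=1) - rvals.mean(axis=1)

    if len(target_samples) <= _EXACT_MAX_N and len(rest_samples) <= _EXACT_MAX_N:
        pvals = np.array([rank_sum_test(t, r)[1] for t, r in zip(tvals, rvals)])
    else:
        pvals = _vectorized_mwu(tvals, rvals)
    padj = benjamini_hochberg(np.clip(pvals, np.finfo(float).tiny, 1.0))
    table = _diff_table(expr.feature_ids.to_numpy(), log2fc, pvals, padj,
                        lfc_gate, padj_gate, two_sided_lfc=False)
    if per_entity:
        lfc_ok = np.ones(len(table), dtype=bool)
        for entity in expr.entities():
            if entity == target_entity:
                continue
            evals = expr.values[expr.samples_of(entity)].to_numpy()
            lfc_ok &= (tvals.mean(axis=1) - evals.mean(axis=1)) > lfc_gate
        table["pass"] &= lfc_ok
    passing = set(table.loc[table["pass"], "feature"])
    return table, passing


def dep_knockdown_concordance(
    kd_tables: dict[str, tuple[pd.DataFrame, pd.DataFrame]],
    lfc_gate: float = 1.0, padj_gate: float = 0.01,
) -> tuple[dict[str, pd.DataFrame], set[str]]:
    """Knockdown-vs-control differential proteomics, concordant across lines.

    ``kd_tables`` maps cell-line name -> (control, knockdown) replicate
    frames (proteins x replicates, log2 abundances). Per line: log2FC =
    mean(KD) - mean(control), Welch t per protein, BH within line. A protein
    is concordant when |log2FC| > ``lfc_gate`` and padj < ``padj_gate`` in
    EVERY line with the same sign of regulation throughout.
    """
    if len(kd_tables) < 2:
        raise ValueError("need >= 2 cell lines for concordance")
    tables: dict[str, pd.DataFrame] = {}
    universe: pd.Index | None = None
    for line, (ctrl, kd) in kd_tables.items():
        if ctrl.shape[1] < 3 or kd.shape[1] < 3:
            raise ValueError(
                f"cell line {line!r}: need >= 3 control and >= 3 knockdown "
                "replicates")
        if universe is None:
            universe = ctrl.index
        elif not ctrl.index.equals(universe):
            ctrl = ctrl.reindex(universe)
            kd = kd.reindex(universe)
            if ctrl.isna().any().any() or kd.isna().any().any():
                raise ValueError("cell lines must share the protein universe")
        log2fc = kd.to_numpy().mean(axis=1) - ctrl.to_numpy().mean(axis=1)
        t, p = stats.ttest_ind(kd.to_numpy(), ctrl.to_numpy(), axis=1,
                               equal_var=False)
        p = np.clip(np.nan_to_num(p, nan=1.0), np.finfo(float).tiny, 1.0)
        padj = benjamini_hochberg(p)
        tables[line] = _diff_table(universe.to_numpy(), log2fc, p, padj,
                                   lfc_gate, padj_gate, two_sided_lfc=True)

    concordant_mask = None
    sign_ref = None
    for table in tables.values():
        passing = table["pass"].to_numpy()
        sign = np.sign(table["log2fc"].to_numpy())
        if concordant_mask is None:
            concordant_mask = passing.copy()
            sign_ref = sign
        else:
            concordant_mask &= passing & (sign == sign_ref)
    assert universe is not None and concordant_mask is not None
    return tables, set(universe.to_numpy()[concordant_mask])
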