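"""Rank-sum test, BH adjustment, and the two differential gates."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from markernom import (ExpressionMatrix, benjamini_hochberg, deg_one_vs_rest,
                       dep_knockdown_concordance, rank_sum_test)


def bh_oracle(p):
    """Literal step-up: padj_i = min_{j>=rank(i)} m p_(j)/j, capped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    out = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        out[i] = min(running, 1.0)
    return out


class TestRankSum:
    def test_identical_multisets_give_p_one(self):
        _, p = rank_sum_test([1, 2, 2, 5], [1, 2, 2, 5])
        assert p == 1.0

    def test_fully_separated_three_vs_three(self):
        u, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)

    def test_two_vs_one(self):
        u, p = rank_sum_test([1, 2], [3])
        assert u == 0
        assert p == pytest.approx(2 / 3)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.data())
    def test_exact_mode_matches_scipy_exact_without_ties(self, data):
        # distinct values so scipy's exact permutation distribution applies
        n1 = data.draw(st.integers(1, 6))
        n2 = data.draw(st.integers(1, 6))
        values = data.draw(st.lists(
            st.floats(-100, 100, allow_nan=False),
            min_size=n1 + n2, max_size=n1 + n2, unique=True))
        a, b = values[:n1], values[n1:]
        u, p = rank_sum_test(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.03])[0] == pytest.approx(0.03)

    def test_worked_example_all_collapse_to_largest(self):
        out = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_one(self):
        assert np.all(benjamini_hochberg([1.0, 1.0, 1.0]) == 1.0)

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [-0.1], [1.2], [np.nan]])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            benjamini_hochberg(bad)

    def test_matches_step_up_oracle_on_random_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            m = int(rng.integers(1, 51))
            p = rng.uniform(1e-8, 1.0, m)
            assert np.max(np.abs(benjamini_hochberg(p) - bh_oracle(p))) < 1e-12

    def test_adjustment_never_decreases_p(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(1e-6, 1, 100)
        assert np.all(benjamini_hochberg(p) >= p)


def _matrix(values, labels):
    df = pd.DataFrame(values)
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    df.index = [f"g{i}" for i in range(df.shape[0])]
    return ExpressionMatrix(values=df,
                            entity_labels=pd.Series(labels, index=df.columns))


class TestDegOneVsRest:
    def test_recovers_planted_biomarkers(self, bundle42):
        table, passing = deg_one_vs_rest(bundle42.expression, "DSRCT")
        assert set(bundle42.truth.planted_biomarkers) <= passing
        t = table.set_index("feature")
        assert (t.loc[bundle42.truth.planted_biomarkers, "log2fc"] > 2.5).all()

    def test_infinite_gate_passes_nothing(self, bundle42):
        _, passing = deg_one_vs_rest(bundle42.expression, "DSRCT",
                                     lfc_gate=np.inf)
        assert passing == set()

    def test_null_matrix_passes_nothing(self):
        rng = np.random.default_rng(2)
        expr = _matrix(rng.normal(6, 1, (50, 20)), ["T"] * 10 + ["M"] * 10)
        _, passing = deg_one_vs_rest(expr, "T")
        assert passing == set()

    def test_unknown_entity_rejected(self, tiny_expr):
        with pytest.raises(KeyError):
            deg_one_vs_rest(tiny_expr, "NOPE")

    def test_invariant_to_column_order_and_constant_shift(self, bundle42):
        expr = bundle42.expression
        table, _ = deg_one_vs_rest(expr, "DSRCT")
        rng = np.random.default_rng(0)
        perm = rng.permutation(expr.values.columns)
        shuffled = ExpressionMatrix(values=expr.values[perm] + 7.0,
                                    entity_labels=expr.entity_labels[perm])
        table2, _ = deg_one_vs_rest(shuffled, "DSRCT")
        assert np.allclose(table["log2fc"], table2["log2fc"])
        assert np.allclose(table["pvalue"], table2["pvalue"])

    def test_per_entity_mode_is_stricter(self, bundle42):
        _, pooled = deg_one_vs_rest(bundle42.expression, "DSRCT")
        _, strict = deg_one_vs_rest(bundle42.expression, "DSRCT",
                                    per_entity=True)
        assert strict <= pooled
        assert set(bundle42.truth.planted_biomarkers) <= strict


class TestDepConcordance:
    def test_recovers_planted_proteins(self, bundle42):
        _, concordant = dep_knockdown_concordance(bundle42.kd_tables)
        planted = (set(bundle42.truth.planted_biomarkers)
                   | set(bundle42.truth.kd_program_proteins))
        assert planted <= concordant

    def test_discordant_sign_excluded(self):
        rng = np.random.default_rng(4)
        proteins = [f"p{i}" for i in range(200)]
        def tables(sign_for_p0):
            base = rng.normal(6, 1, 200)
            eff = rng.normal(0, 0.05, 200)
            eff[0] = sign_for_p0 * 3.0
            ctrl = pd.DataFrame(base[:, None] + rng.normal(0, 0.1, (200, 4)),
                                index=proteins)
            kd = pd.DataFrame((base + eff)[:, None]
                              + rng.normal(0, 0.1, (200, 4)), index=proteins)
            return ctrl, kd
        _, concordant = dep_knockdown_concordance(
            {"L1": tables(+1), "L2": tables(-1)})
        assert "p0" not in concordant

    def test_null_effect_gives_empty_set(self):
        from markernom import TruthParams, generate_multiomics
        b = generate_multiomics(TruthParams(dep_effect=0.0, seed=3))
        _, concordant = dep_knockdown_concordance(b.kd_tables)
        assert len(concordant) == 0

    def test_too_few_replicates_rejected(self, bundle42):
        ctrl, kd = bundle42.kd_tables["LINE_A"]
        with pytest.raises(ValueError, match="replicates"):
            dep_knockdown_concordance(
                {"L1": (ctrl.iloc[:, :2], kd), "L2": (ctrl, kd)})

    def test_padj_at_least_pvalue(self, bundle42):
        tables, _ = dep_knockdown_concordance(bundle42.kd_tables)
        for t in tables.values():
            assert (t["padj"] >= t["pvalue"] - 1e-15).all()
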