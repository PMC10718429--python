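import numpy as np
import pytest
from scipy import integrate

from sharpseg.comparison_stats import (DiscordanceCounts, bonferroni_adjust,
                                       compare_models, comparison_table,
                                       discordant_counts, mcnemar_test)


def chi2_upper_tail_by_integration(x: float) -> float:
    """Independent chi-squared(1) survival function: integrate the density."""
    density = lambda t: np.exp(-t / 2.0) / np.sqrt(2.0 * np.pi * t)
    val, _ = integrate.quad(density, x, np.inf)
    return val


def brute_force_counts(pred_a, pred_b, truth):
    b = c = 0
    for pa, pb, t in zip(pred_a.ravel(), pred_b.ravel(), truth.ravel()):
        ok_a, ok_b = pa == t, pb == t
        if ok_a and not ok_b:
            b += 1
        elif ok_b and not ok_a:
            c += 1
    return b, c


class TestDiscordantCounts:
    def test_identical_predictions(self, rng):
        t = (rng.random((3, 4, 4)) < 0.5).astype(np.uint8)
        p = (rng.random((3, 4, 4)) < 0.5).astype(np.uint8)
        counts = discordant_counts(p, p, t)
        assert counts.b == counts.c == 0

    def test_all_ones_vs_all_zeros(self):
        truth = np.ones((1, 2, 2), dtype=np.uint8)
        a = np.ones((1, 2, 2), dtype=np.uint8)
        b = np.zeros((1, 2, 2), dtype=np.uint8)
        counts = discordant_counts(a, b, truth)
        assert (counts.b, counts.c) == (4, 0)
        assert counts.n_pixels == 4

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(20):
            t = (rng.random((2, 8, 8)) < 0.5).astype(np.uint8)
            a = (rng.random((2, 8, 8)) < 0.5).astype(np.uint8)
            b = (rng.random((2, 8, 8)) < 0.5).astype(np.uint8)
            counts = discordant_counts(a, b, t)
            assert (counts.b, counts.c) == brute_force_counts(a, b, t)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            discordant_counts(np.zeros((1, 2, 2), dtype=np.uint8),
                              np.zeros((1, 2, 3), dtype=np.uint8),
                              np.zeros((1, 2, 2), dtype=np.uint8))

    def test_non_binary_rejected(self):
        m = np.full((1, 2, 2), 2, dtype=np.uint8)
        with pytest.raises(ValueError):
            discordant_counts(m, m, m)


class TestMcNemar:
    def _counts(self, b, c):
        return DiscordanceCounts(b=b, c=c, n_images=1, n_pixels=b + c + 10)

    def test_balanced_discordance(self):
        r = mcnemar_test(self._counts(5, 5))
        assert r.statistic == 0.0
        assert r.p_raw == 1.0

    def test_no_discordance_convention(self):
        r = mcnemar_test(self._counts(0, 0))
        assert r.p_raw == 1.0

    def test_8_vs_2(self):
        r = mcnemar_test(self._counts(8, 2))
        assert r.statistic == pytest.approx(3.6)
        assert r.p_raw == pytest.approx(0.0578, abs=2e-4)

    def test_25_vs_5(self):
        r = mcnemar_test(self._counts(25, 5))
        assert r.statistic == pytest.approx(13.3333, abs=1e-3)
        assert r.p_raw < 0.001

    @pytest.mark.parametrize("b,c", [(8, 2), (25, 5), (100, 70), (3, 1)])
    def test_p_value_agrees_with_numerical_integration(self, b, c):
        r = mcnemar_test(self._counts(b, c))
        assert r.p_raw == pytest.approx(
            chi2_upper_tail_by_integration(r.statistic), abs=1e-6)

    @pytest.mark.parametrize("b,c", [(8, 2), (30, 12)])
    def test_swap_invariance(self, b, c):
        assert mcnemar_test(self._counts(b, c)).statistic == \
            mcnemar_test(self._counts(c, b)).statistic
        assert mcnemar_test(self._counts(b, c)).p_raw == \
            mcnemar_test(self._counts(c, b)).p_raw

    def test_p_decreases_with_imbalance(self):
        total = 200
        ps = [mcnemar_test(self._counts(total // 2 + d, total // 2 - d)).p_raw
              for d in (0, 10, 20, 40)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_exact_binomial_fallback(self):
        from scipy import stats
        r = mcnemar_test(self._counts(8, 2), exact=True)
        assert r.p_raw == pytest.approx(stats.binomtest(2, 10, 0.5).pvalue)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar
        for b, c in ((8, 2), (40, 25)):
            table = [[0, b], [c, 0]]
            ref = sm_mcnemar(table, exact=False, correction=False)
            r = mcnemar_test(self._counts(b, c))
            assert r.statistic == pytest.approx(float(ref.statistic))
            assert r.p_raw == pytest.approx(float(ref.pvalue), abs=1e-12)


class TestBonferroni:
    def test_multiplication(self):
        assert bonferroni_adjust([0.005], m=6) == [pytest.approx(0.03)]

    def test_cap_at_one(self):
        assert bonferroni_adjust([0.5], m=6) == [1.0]

    def test_order_preserved(self, rng):
        ps = sorted(rng.random(10))
        adj = bonferroni_adjust(ps, m=12)
        assert adj == sorted(adj)

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([1.5], m=2)
        with pytest.raises(ValueError):
            bonferroni_adjust([0.1, 0.2], m=1)


class TestCompareModels:
    def test_identical_models_not_significant(self, rng):
        t = (rng.random((2, 6, 6)) < 0.5).astype(np.uint8)
        p = (rng.random((2, 6, 6)) < 0.5).astype(np.uint8)
        res = compare_models({"a": p, "b": p.copy()}, t)
        r = res[("a", "b")]
        assert r.p_adjusted == 1.0
        assert not r.significant

    def test_four_models_six_pairs(self, rng):
        t = (rng.random((2, 8, 8)) < 0.5).astype(np.uint8)
        preds = {k: (rng.random((2, 8, 8)) < 0.5).astype(np.uint8)
                 for k in "abcd"}
        res = compare_models(preds, t)
        assert len(res) == 6
        # family alpha 0.1 over six pairs: per-test cutoff 0.1/6 < 0.02
        assert 0.1 / 6 == pytest.approx(0.0167, abs=1e-3)
        for r in res.values():
            assert r.p_adjusted == pytest.approx(min(1.0, 6 * r.p_raw))
        table = comparison_table(res)
        assert table.shape == (4, 4)
        assert np.isnan(table.values[np.triu_indices(4)]).all()

    def test_pair_order_symmetry(self, rng):
        t = (rng.random((1, 8, 8)) < 0.5).astype(np.uint8)
        a = (rng.random((1, 8, 8)) < 0.5).astype(np.uint8)
        b = (rng.random((1, 8, 8)) < 0.5).astype(np.uint8)
        r_ab = compare_models({"a": a, "b": b}, t)[("a", "b")]
        r_ba = compare_models({"b": b, "a": a}, t)[("b", "a")]
        assert r_ab.statistic == r_ba.statistic
        assert r_ab.counts.b == r_ba.counts.c

    def test_single_model_rejected(self, rng):
        t = np.zeros((1, 2, 2), dtype=np.uint8)
        with pytest.raises(ValueError):
            compare_models({"a": t}, t)
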