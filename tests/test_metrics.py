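"""Agreement statistics against independent brute-force oracles.

Each statistic is recomputed with the direct textbook formula in
extended precision (math on Python floats via np.longdouble) and
compared to the implementation at 1e-10 relative tolerance.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from elastnet import (
    AgreementReport,
    bland_altman,
    compute_agreement,
    error_fractions,
    nrmse,
    pearson_r,
)


def _oracle_pearson(x, y):
    x = np.asarray(x, dtype=np.longdouble)
    y = np.asarray(y, dtype=np.longdouble)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))


def _oracle_nrmse(pred, ref):
    pred = np.asarray(pred, dtype=np.longdouble)
    ref = np.asarray(ref, dtype=np.longdouble)
    rmse = np.sqrt(((pred - ref) ** 2).mean())
    return float(100.0 * rmse / (ref.max() - ref.min()))


def _oracle_ols(x, y):
    x = np.asarray(x, dtype=np.longdouble)
    y = np.asarray(y, dtype=np.longdouble)
    slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
    return float(slope), float(y.mean() - slope * x.mean())


class TestPearson:
    def test_perfect_agreement(self):
        r, _ = pearson_r([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        r, _ = pearson_r([1.0, 2.0, 3.0], [4.0, 3.0, 2.0])
        assert r == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        r, p = pearson_r([1, 2, 3, 5], [1, 2, 3, 4])
        assert r == pytest.approx(0.9827, abs=1e-4)
        assert 0 < p < 0.05

    def test_p_value_follows_wald_t(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        r, p = pearson_r(x, y)
        from scipy import stats

        t = r * np.sqrt((30 - 2) / (1 - r**2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 28), rel=1e-8)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestNRMSE:
    def test_zero_for_identical(self):
        assert nrmse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_hand_computed_example(self):
        assert nrmse([1, 2, 3], [1, 2, 4]) == pytest.approx(19.245, abs=1e-3)

    def test_translation_invariance(self):
        a = nrmse([1.0, 2.2, 2.9], [1.0, 2.0, 3.0])
        b = nrmse([8.0, 9.2, 9.9], [8.0, 9.0, 10.0])
        assert a == pytest.approx(b)

    def test_zero_range_rejected(self):
        with pytest.raises(ValueError):
            nrmse([1.0, 2.0], [3.0, 3.0])


class TestBlandAltman:
    def test_no_difference(self):
        assert bland_altman([1.0, 2.0], [1.0, 2.0]) == (0.0, 0.0, 0.0)

    def test_symmetric_differences(self):
        bias, lo, hi = bland_altman([1.1, 1.9], [1.0, 2.0])
        assert bias == pytest.approx(0.0)
        assert hi == pytest.approx(1.96 * np.sqrt(0.02), abs=1e-9)  # ~0.2772
        assert lo == pytest.approx(-hi)

    def test_constant_offset(self):
        bias, lo, hi = bland_altman([1.5, 2.5, 3.5], [1.0, 2.0, 3.0])
        assert (bias, lo, hi) == (0.5, 0.5, 0.5)

    def test_sign_convention_predicted_minus_reference(self):
        bias, *_ = bland_altman([2.36] * 4, [2.40] * 4)
        assert bias == pytest.approx(-0.04)


class TestErrorFractions:
    def test_perfect_predictions(self):
        f = error_fractions([1.0, 2.0], [1.0, 2.0], [0.05, 0.5])
        assert f == {0.05: 1.0, 0.5: 1.0}

    def test_counting(self):
        f = error_fractions([1.01, 2.1, 3.6], [1.0, 2.0, 3.0], [0.5])
        assert f[0.5] == pytest.approx(2 / 3)

    def test_strict_inequality(self):
        f = error_fractions([1.5], [1.0], [0.5])
        assert f[0.5] == 0.0

    @settings(deadline=None, max_examples=20)
    @given(st.integers(0, 2**31 - 1))
    def test_monotone_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        pred, ref = rng.normal(2.3, 0.8, size=(2, 50))
        f = error_fractions(pred, ref, [0.01, 0.05, 0.2, 0.5, 1.0, 5.0])
        vals = [f[t] for t in sorted(f)]
        assert np.all(np.diff(vals) >= 0)


class TestAgainstOracles:
    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2**31 - 1), st.sampled_from([10, 100, 1000, 10000]))
    def test_all_statistics_match_brute_force(self, seed, n):
        rng = np.random.default_rng(seed)
        ref = rng.normal(2.4, 0.8, size=n)
        pred = ref + rng.normal(0, 0.3, size=n)
        rep = compute_agreement(pred, ref)
        assert rep.r == pytest.approx(_oracle_pearson(pred, ref), rel=1e-10, abs=1e-12)
        assert rep.nRMSE == pytest.approx(_oracle_nrmse(pred, ref), rel=1e-10)
        slope, intercept = _oracle_ols(ref, pred)
        assert rep.slope == pytest.approx(slope, rel=1e-10)
        assert rep.intercept == pytest.approx(intercept, rel=1e-10, abs=1e-10)
        d = pred - ref
        assert rep.bias == pytest.approx(float(np.mean(d)), rel=1e-10, abs=1e-14)
        sd = float(np.std(d, ddof=1))
        assert rep.loa_high == pytest.approx(rep.bias + 1.96 * sd, rel=1e-10)

    @settings(deadline=None, max_examples=15)
    @given(st.integers(0, 2**31 - 1))
    def test_regression_residual_orthogonality(self, seed):
        rng = np.random.default_rng(seed)
        ref = rng.normal(2.4, 0.8, size=200)
        pred = 0.8 * ref + rng.normal(0, 0.2, size=200)
        rep = compute_agreement(pred, ref)
        resid = pred - (rep.slope * ref + rep.intercept)
        # normal equations: residuals orthogonal to [1, ref]
        assert abs(resid.sum()) < 1e-8
        assert abs((resid * ref).sum()) < 1e-7


class TestAgreementReport:
    def test_json_round_trip(self):
        rng = np.random.default_rng(42)
        ref = rng.normal(2.4, 0.8, size=50)
        rep = compute_agreement(ref + rng.normal(0, 0.1, 50), ref, label="demo")
        again = AgreementReport.from_json(rep.to_json())
        assert again == rep

    def test_invariant_validation(self):
        with pytest.raises(ValueError):
            AgreementReport(
                label="bad", n=3, slope=1, intercept=0, r=0.5, p_value=0.1,
                RMSE=0.1, nRMSE=1.0, bias=0.5, loa_low=0.6, loa_high=0.7,
                pred_mean=2.0, pred_sd=0.5,
            )
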