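"""LLD estimation, logistic detection curves and the background simulation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import petlimit as pl
from petlimit import detection
from petlimit.errors import (
    InestimableError,
    NoFiniteLLDError,
    SingularFitError,
    ValidationError,
)


# --------------------------------------------------------------------------
# independent four-step LLD oracle (numpy/scipy only, no statsmodels)


def lld_oracle(cells, sa, y, rule="ci95_upper", ci_at=0.0):
    def ols(x, y):
        n = len(x)
        xbar, ybar = x.mean(), y.mean()
        sxx = ((x - xbar) ** 2).sum()
        slope = ((x - xbar) * (y - ybar)).sum() / sxx
        intercept = ybar - slope * xbar
        resid = y - intercept - slope * x
        s2 = (resid**2).sum() / (n - 2)
        return slope, intercept, s2, xbar, sxx, n

    s_sa = ols(sa, y)
    s_cells = ols(cells, y)
    if rule == "ci95_upper":
        slope, intercept, s2, xbar, sxx, n = s_sa
        se_mean = np.sqrt(s2 * (1 / n + (ci_at - xbar) ** 2 / sxx))
        t = stats.t.ppf(0.975, n - 2)
        thr = intercept + slope * ci_at + t * se_mean
    else:
        thr = 5.0
    out = {}
    for name, (slope, intercept, *_rest) in (("cells", s_cells), ("sa", s_sa)):
        if slope <= 0:
            out[name] = None
        else:
            out[name] = (thr - intercept) / slope
    return thr, out["cells"], out["sa"]


def make_well_frame(cells, sa, y, excluded=None):
    df = pd.DataFrame(
        {
            "cnr": y,
            "cell_number": cells,
            "specific_activity_kBq_per_1e6": sa,
        }
    )
    df["qc_excluded"] = excluded if excluded is not None else False
    return df


class TestFitLine:
    def test_exact_line(self):
        x = np.array([0.0, 1, 2, 3, 4])
        fit = pl.fit_line(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-10)
        lo, hi = fit.mean_ci(10.0)
        assert hi[0] - lo[0] == pytest.approx(0.0, abs=1e-9)

    def test_too_few_points(self):
        with pytest.raises(SingularFitError):
            pl.fit_line([1, 2], [1, 2])

    def test_constant_predictor(self):
        with pytest.raises(SingularFitError):
            pl.fit_line([3, 3, 3, 3], [1, 2, 3, 4])

    def test_monte_carlo_slope_recovery(self, rng):
        x = rng.uniform(0, 10, 1000)
        y = 3 * x + rng.normal(0, 1, 1000)
        fit = pl.fit_line(x, y)
        assert 2.9 < fit.slope < 3.1


class TestEstimateLld:
    def test_rose_rule_algebraic_inversion(self):
        cells = np.linspace(100, 2000, 12)
        y = 0.01 * cells  # exact line through origin
        sa = np.linspace(1, 20, 12)
        df = make_well_frame(cells, sa, y)
        res = pl.estimate_lld(df, rule="rose")
        assert res.cnr_threshold == 5.0
        assert res.lld_cells == pytest.approx(500.0, rel=1e-9)

    def test_all_excluded_is_error(self):
        df = make_well_frame([1, 2, 3, 4], [1, 2, 3, 4], [1, 2, 3, 4], excluded=True)
        with pytest.raises(SingularFitError):
            pl.estimate_lld(df)

    def test_nonpositive_slope_no_finite_lld(self, rng):
        cells = np.linspace(100, 2000, 20)
        df = make_well_frame(cells, np.linspace(1, 5, 20), -0.01 * cells + 30)
        with pytest.raises(NoFiniteLLDError):
            pl.estimate_lld(df, rule="rose")

    def test_equivalence_with_independent_oracle(self, rng):
        """estimate_lld matches an independently coded four-step oracle on
        50 random synthetic tables (relative error <= 1e-9)."""
        for _ in range(50):
            n = int(rng.integers(10, 40))
            cells = rng.uniform(1e4, 1e6, n)
            sa = rng.uniform(0.4, 32, n)
            y = (
                2e-4 * cells
                + rng.uniform(0.5, 3) * sa
                + rng.normal(0, rng.uniform(1, 30), n)
            )
            df = make_well_frame(cells, sa, y)
            thr, lcells, lsa = lld_oracle(cells, sa, y)
            if lcells is None or lsa is None or lcells <= 0:
                continue
            res = pl.estimate_lld(df, rule="ci95_upper")
            assert res.cnr_threshold == pytest.approx(thr, rel=1e-9)
            assert res.lld_cells == pytest.approx(lcells, rel=1e-9)
            assert res.lld_specific_activity == pytest.approx(lsa, rel=1e-9)


class TestRoseClassify:
    @pytest.mark.parametrize(
        "value,expected", [(5.0, True), (4.999, False), (2106.0, True), (-1.0, False)]
    )
    def test_boundary_and_range(self, value, expected):
        assert pl.rose_classify(value) is expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            pl.rose_classify(float("nan"))


class TestLogistic:
    def test_parameter_recovery(self, rng):
        """Data sampled from the logistic model (beta0=-4, beta1=1e-5,
        n=5000): both coefficients recovered within 10 %."""
        beta0, beta1 = -4.0, 1e-5
        x = rng.uniform(0, 1.2e6, 5000)
        p = 1 / (1 + np.exp(-(beta0 + beta1 * x)))
        d = rng.random(5000) < p
        curve = pl.fit_logistic(x, d)
        assert curve.beta0 == pytest.approx(beta0, rel=0.10)
        assert curve.beta1 == pytest.approx(beta1, rel=0.10)
        assert not curve.ridge_fallback

    def test_single_class_inestimable(self):
        with pytest.raises(InestimableError):
            pl.fit_logistic([1, 2, 3], [True, True, True])

    def test_permutation_invariance(self, rng):
        x = rng.uniform(0, 1e6, 200)
        d = x > 4e5
        d[::7] = ~d[::7]
        perm = rng.permutation(200)
        a = pl.fit_logistic(x, d)
        b = pl.fit_logistic(x[perm], d[perm])
        assert a.beta0 == pytest.approx(b.beta0, rel=1e-6)
        assert a.beta1 == pytest.approx(b.beta1, rel=1e-6)

    def test_separated_data_uses_flagged_ridge(self):
        x = np.linspace(0, 1e6, 50)
        curve = pl.fit_logistic(x, x > 5e5)
        assert curve.ridge_fallback
        assert curve.beta1 > 0

    def test_probability_midpoint_and_flat_curve(self):
        curve = pl.DetectionCurve(beta0=-2.0, beta1=0.5)
        assert pl.detection_probability(curve, 4.0) == pytest.approx(0.5)
        flat = pl.DetectionCurve(beta0=np.log(9), beta1=0.0)
        for x in (0.0, 1e3, 1e7):
            assert pl.detection_probability(flat, x) == pytest.approx(0.9)

    def test_probability_strictly_increasing(self):
        curve = pl.DetectionCurve(beta0=-4.0, beta1=1e-5)
        x = np.linspace(0, 2e6, 100)
        p = pl.detection_probability(curve, x)
        assert np.all(np.diff(p) > 0)

    def test_cells_at_probability_closed_form(self):
        curve = pl.DetectionCurve(beta0=-4.59512, beta1=1e-5)
        expected = (np.log(9.0) + 4.59512) / 1e-5  # = 679234.46
        assert pl.cells_at_probability(curve, 0.9) == pytest.approx(expected)
        assert pl.cells_at_probability(curve, 0.5) == pytest.approx(4.59512e5)

    def test_round_trip_inverse(self):
        curve = pl.DetectionCurve(beta0=-3.3, beta1=2.7e-6)
        for p in (0.1, 0.5, 0.9, 0.99):
            x = pl.cells_at_probability(curve, p)
            assert pl.detection_probability(curve, x) == pytest.approx(p, abs=1e-12)

    def test_beta1_zero_has_no_inverse(self):
        with pytest.raises(NoFiniteLLDError):
            pl.cells_at_probability(pl.DetectionCurve(beta0=0.0, beta1=0.0), 0.9)


def small_mu_frame(mu_values, cells=None):
    n = len(mu_values)
    return pd.DataFrame(
        {
            "well_id": [f"w{i}" for i in range(n)],
            "mu_w": mu_values,
            "cell_number": cells if cells is not None else np.linspace(1e4, 1e6, n),
        }
    )


class TestBackgroundSimulation:
    def test_dataset_count_is_wells_times_fractions(self):
        df = small_mu_frame(np.linspace(0.01, 2.0, 31))
        out = pl.simulate_background_levels(df, k=1e-3)
        assert len(out) == 31 * 8

    def test_cnr_formula_exact(self):
        """CNR(f) = mu (1 - f) / sqrt(k f mu) for every well and fraction."""
        df = small_mu_frame([0.5, 1.7])
        k = 2.5e-3
        out = pl.simulate_background_levels(df, k=k)
        expected = (
            out.mu_w * (1 - out.background_fraction)
            / np.sqrt(k * out.background_fraction * out.mu_w)
        )
        np.testing.assert_allclose(out.cnr, expected, rtol=1e-12)

    def test_full_background_fraction_nulls_cnr(self):
        df = small_mu_frame([0.8])
        out = pl.simulate_background_levels(df, fractions=[1.0], k=1e-3)
        assert out.cnr.iloc[0] == pytest.approx(0.0)

    def test_cnr_strictly_decreasing_in_fraction(self):
        df = small_mu_frame([0.9])
        out = pl.simulate_background_levels(df, k=1e-3).sort_values(
            "background_fraction"
        )
        assert np.all(np.diff(out.cnr) < 0)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValidationError):
            pl.simulate_background_levels(small_mu_frame([0.5]), k=0.0)

    def test_doubling_signal_scales_cnr_by_sqrt2(self):
        df = small_mu_frame(np.linspace(0.05, 1.0, 10))
        df2 = df.assign(mu_w=2 * df.mu_w)
        a = pl.simulate_background_levels(df, k=1e-3)
        b = pl.simulate_background_levels(df2, k=1e-3)
        np.testing.assert_allclose(b.cnr, np.sqrt(2) * a.cnr, rtol=1e-12)
        assert b.detected.sum() >= a.detected.sum()

    def test_all_inestimable_is_flagged_not_fatal(self):
        df = small_mu_frame([5.0, 6.0, 7.0])  # all detected at every fraction
        out = pl.simulate_background_levels(df, k=1e-6)
        curves = pl.detection_vs_background(out)
        assert not curves.estimable.any()
        assert (curves.bound == "upper").all()

    def test_ninety_point_grows_with_background(self, detection_reports):
        """Default study: the 90 %-point at f=0.8 exceeds the f=0.1 value by
        at least 10x (scaled-down version of the two-orders-of-magnitude
        growth), and the trend over fractions is increasing."""
        for rep in detection_reports.values():
            curves = rep.background_curves
            assert len(rep.background_set) == 248
            low = curves.loc[
                curves.background_fraction == 0.1, "cells_at_p_bound"
            ].iloc[0]
            high = curves.loc[
                curves.background_fraction == 0.8, "cells_at_p_bound"
            ].iloc[0]
            assert high >= 10 * low
            rho = stats.spearmanr(
                curves.background_fraction, curves.cells_at_p_bound
            ).statistic
            assert rho > 0.5
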