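"""Dose/risk equations, Monte Carlo propagation, bounds and classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pitchrisk.risk import (
    DermalRiskModel,
    ExposureParameters,
    ParameterDistribution,
    TABLE_DEFAULTS,
    absorbed_daily_intake,
    carcinogenic_risk,
    classify_risk,
    deterministic_bounds,
    monte_carlo_risk,
    round_sig,
)

MAXIMA = dict(C=591.31, AF=0.08, ABS=0.03, CF=1e-6, SA=5700.0, EV=3.0,
              EF=80.0, ED=13.0, BW=74.8, AT=25550.0)
MINIMA = dict(C=13.14, AF=0.01, ABS=0.03, CF=1e-6, SA=3300.0, EV=1.0,
              EF=3.0, ED=0.083, BW=74.8, AT=25550.0)


def _dists_spanning_ranges():
    dists = {}
    for name, (lo, hi) in TABLE_DEFAULTS.items():
        if lo == hi:
            dists[name] = ParameterDistribution.point(name, lo)
        else:
            dists[name] = ParameterDistribution.empirical(
                name, np.linspace(lo, hi, 25))
    return dists


class TestDoseEquation:
    def test_adi_at_all_maxima(self):
        """Direct product/quotient of the worst-case parameter vector."""
        adi = absorbed_daily_intake(ExposureParameters(**MAXIMA))
        assert adi == pytest.approx(1.3206e-5, rel=1e-4)

    def test_adi_at_all_minima(self):
        adi = absorbed_daily_intake(ExposureParameters(**MINIMA))
        assert adi == pytest.approx(1.695e-12, rel=1e-3)

    def test_linearity_in_concentration(self):
        base = absorbed_daily_intake(ExposureParameters(**MAXIMA))
        doubled = absorbed_daily_intake(
            ExposureParameters(**{**MAXIMA, "C": 2 * MAXIMA["C"]}))
        assert doubled == pytest.approx(2 * base, rel=1e-12)

    def test_nonpositive_parameter_named_in_error(self):
        with pytest.raises(ValueError, match="EF"):
            absorbed_daily_intake(ExposureParameters(**{**MAXIMA, "EF": 0.0}))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_monotone_in_every_parameter(self, seed):
        """Risk rises with any numerator parameter, falls with BW or AT."""
        rng = np.random.default_rng(seed)
        params = {n: rng.uniform(lo, hi) if lo < hi else lo
                  for n, (lo, hi) in TABLE_DEFAULTS.items()}
        base = carcinogenic_risk(absorbed_daily_intake(ExposureParameters(**params)))
        for name in ("C", "AF", "SA", "EV", "EF", "ED"):
            bumped = {**params, name: params[name] * 1.1}
            assert carcinogenic_risk(absorbed_daily_intake(
                ExposureParameters(**bumped))) > base
        for name in ("BW", "AT"):
            bumped = {**params, name: params[name] * 1.1}
            assert carcinogenic_risk(absorbed_daily_intake(
                ExposureParameters(**bumped))) < base

    def test_scale_invariance_c_against_af(self):
        """Risk is unchanged when C is multiplied by k and AF divided by k."""
        a = ExposureParameters(**MAXIMA)
        b = ExposureParameters(**{**MAXIMA, "C": MAXIMA["C"] * 4.0,
                                  "AF": MAXIMA["AF"] / 4.0})
        assert carcinogenic_risk(absorbed_daily_intake(a)) == pytest.approx(
            carcinogenic_risk(absorbed_daily_intake(b)), rel=1e-12)


class TestRiskEquation:
    def test_published_adi_times_slope_factor(self):
        """ADI 5e-6 with SF 3.66 gives the reported maximum risk 1.8e-5."""
        assert round_sig(carcinogenic_risk(5e-6, 3.66), 2) == 1.8e-5

    def test_zero_dose_zero_risk(self):
        assert carcinogenic_risk(0.0, 3.66) == 0.0

    def test_maxima_derived_risk(self):
        adi = absorbed_daily_intake(ExposureParameters(**MAXIMA))
        assert carcinogenic_risk(adi) == pytest.approx(4.83e-5, rel=1e-3)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError, match="ADI"):
            carcinogenic_risk(-1e-9)


class TestDeterministicBounds:
    def test_default_ranges(self):
        lower, upper = deterministic_bounds()
        assert lower == pytest.approx(6.20e-12, rel=1e-3)
        assert upper == pytest.approx(4.83e-5, rel=1e-3)

    def test_published_range_inside_bounds(self):
        """The reported stochastic range must be bracketed by the bounds."""
        lower, upper = deterministic_bounds()
        assert lower <= 1.0e-10 and 1.8e-5 <= upper

    def test_collapsed_ranges_meet(self):
        point_ranges = {n: (v, v) for n, v in MAXIMA.items()}
        lower, upper = deterministic_bounds(point_ranges)
        assert lower == upper

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError, match="inverted"):
            deterministic_bounds({"C": (10.0, 5.0)})


class TestMonteCarlo:
    def test_degenerate_points_equal_deterministic(self):
        dists = {n: ParameterDistribution.point(n, v) for n, v in MAXIMA.items()}
        res = monte_carlo_risk(dists, n_iter=10, seed=0)
        np.testing.assert_allclose(res.samples, 4.833e-5, rtol=1e-3)
        assert res.lower_bound == pytest.approx(res.upper_bound)

    def test_bracketing_by_deterministic_bounds(self):
        res = monte_carlo_risk(_dists_spanning_ranges(), n_iter=10_000, seed=1)
        assert res.samples.min() >= res.lower_bound
        assert res.samples.max() <= res.upper_bound
        assert res.lower_bound == pytest.approx(6.20e-12, rel=1e-3)
        assert res.upper_bound == pytest.approx(4.83e-5, rel=1e-3)

    def test_single_iteration_reproducible(self):
        dists = _dists_spanning_ranges()
        a = monte_carlo_risk(dists, n_iter=1, seed=99)
        b = monte_carlo_risk(dists, n_iter=1, seed=99)
        assert a.samples[0] == b.samples[0]

    def test_missing_parameter_named(self):
        dists = _dists_spanning_ranges()
        del dists["AF"]
        with pytest.raises(ValueError, match="AF"):
            monte_carlo_risk(dists, n_iter=10)

    def test_all_risks_positive(self):
        res = monte_carlo_risk(_dists_spanning_ranges(), n_iter=1000, seed=4)
        assert (res.samples > 0).all()


class TestClassification:
    def test_reported_maximum_exceeds_strict_by_one_order(self):
        c = classify_risk(1.8e-5)
        assert c.exceeds_strict and not c.exceeds_upper
        assert c.within_band
        assert c.orders_above_strict == 1

    def test_below_strict_acceptable(self):
        c = classify_risk(9e-7)
        assert not c.exceeds_strict and not c.exceeds_upper
        assert c.label == "acceptable"

    def test_above_band(self):
        c = classify_risk(2e-4)
        assert c.exceeds_strict and c.exceeds_upper


class TestModelInterface:
    def test_from_tables_fit_and_summary(self, primary_soil, survey_table):
        from pitchrisk.io import survey_exposure_frame

        exposure = survey_exposure_frame(survey_table)
        model = DermalRiskModel.from_tables(primary_soil, exposure)
        results = model.fit(n_iter=2000, seed=0)
        assert results.risk_samples.shape == (2000,)
        lower, upper = results.bounds
        assert lower <= results.min_risk <= results.max_risk <= upper
        text = results.summary()
        assert "max risk" in text and "classification" in text

    def test_joint_resampling_preserves_row_support(self, primary_soil, survey_table):
        from pitchrisk.io import survey_exposure_frame

        exposure = survey_exposure_frame(survey_table)
        model = DermalRiskModel.from_tables(primary_soil, exposure, joint=True)
        results = model.fit(n_iter=500, seed=0)
        assert (results.risk_samples > 0).all()
        assert results.max_risk <= results.bounds[1]

    def test_fit_reproducible(self, primary_soil, survey_table):
        from pitchrisk.io import survey_exposure_frame

        exposure = survey_exposure_frame(survey_table)
        model = DermalRiskModel.from_tables(primary_soil, exposure)
        a = model.fit(n_iter=100, seed=5).risk_samples
        b = model.fit(n_iter=100, seed=5).risk_samples
        np.testing.assert_array_equal(a, b)
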