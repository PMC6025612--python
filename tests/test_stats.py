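"""Zone statistics, Tukey fence screening, group comparison, mass loading."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pitchrisk.stats import (
    IrrigationSpec,
    annual_arsenic_load,
    compare_zones,
    cumulative_load,
    depth_profile,
    fold_exceedance,
    mean_after_removal,
    quartiles,
    screen_extreme_outliers,
    truncate_decimals,
    upper_outer_fence,
    zone_summary,
)


def _soil(values, zone="NIA"):
    return pd.DataFrame({
        "sample_id": [f"S{i:02d}" for i in range(1, len(values) + 1)],
        "zone": zone, "tAs": values,
    })


class TestQuartiles:
    def test_conventions_against_enumerated_oracle(self):
        """Median-split quartiles of 1..9 computed both ways by hand.

        Exclusive split: halves {1..4} and {6..9}, medians 2.5 and 7.5.
        Interpolated (linear): positions 0.25*(9-1)=2 and 6 -> values 3, 7.
        """
        data = range(1, 10)
        assert quartiles(data, "tukey") == (2.5, 7.5)
        assert quartiles(data, "linear") == (3.0, 7.0)

    def test_even_n_conventions_agree_on_halves(self):
        data = [1, 2, 3, 4, 5, 6, 7, 8]
        assert quartiles(data, "tukey") == (2.5, 6.5)

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValueError, match="convention"):
            quartiles([1, 2, 3, 4], "hazen")


class TestZoneSummary:
    def test_bounds_literal_set(self):
        s = zone_summary(_soil([13.1, 100.0, 200.0, 353.3], zone="IA"), "IA")
        assert s.min == 13.1 and s.max == 353.3
        assert s.n == 4

    def test_single_sample_degenerate(self):
        s = zone_summary(_soil([42.0]), "NIA")
        assert s.mean == s.min == s.max == 42.0
        assert s.iqr == 0.0

    def test_order_invariants(self, primary_soil):
        for zone in ("IA", "NIA"):
            s = zone_summary(primary_soil, zone)
            assert s.min <= s.q1 <= s.q3 <= s.max
            assert s.iqr == pytest.approx(s.q3 - s.q1)

    def test_empty_zone_rejected(self):
        with pytest.raises(ValueError, match="IA"):
            zone_summary(_soil([1.0], zone="NIA"), "IA")


class TestOutlierScreen:
    def test_fence_from_printed_quartiles(self):
        """Q3=169.61, IQR=120.28 gives an outer fence of 530.45 < 591.31."""
        fence = upper_outer_fence(169.61, 120.28)
        assert fence == pytest.approx(530.45)
        assert 591.31 > fence

    def test_extreme_value_flagged(self):
        # values chosen so the fence sits below the appended extreme
        base = [50.0, 80.0, 100.0, 130.0, 160.0, 170.0, 180.0]
        table = _soil(base + [591.31])
        screen = screen_extreme_outliers(table)
        flagged = table.set_index("sample_id").loc[list(screen.flagged_ids), "tAs"]
        assert list(flagged) == [591.31]
        assert (screen.retained["tAs"] <= screen.fence).all()

    def test_all_equal_flags_nothing(self):
        screen = screen_extreme_outliers(_soil([5.0] * 6))
        assert screen.n_flagged == 0

    def test_value_exactly_at_fence_not_flagged(self):
        values = [1.0, 2.0, 3.0, 4.0]
        q1, q3 = quartiles(values)
        at_fence = upper_outer_fence(q3, q3 - q1)
        screen = screen_extreme_outliers(_soil(values + [at_fence]))
        # recompute fence for the augmented set; the appended value may move it
        assert all(v <= screen.fence for v in
                   screen.retained["tAs"])

    def test_screen_idempotent_on_retained_set(self, primary_soil):
        first = screen_extreme_outliers(primary_soil)
        second = screen_extreme_outliers(first.retained)
        assert second.n_flagged == 0

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            screen_extreme_outliers(_soil([1.0, 2.0, 3.0]))


class TestMeanAfterRemoval:
    def test_reproduces_printed_zone_mean(self):
        """Removing the 591.31 extreme from the NIA aggregate: 92.5 -> ~59.5."""
        assert mean_after_removal(16, 92.5, 591.31) == pytest.approx(59.5, abs=0.5)

    def test_reproduces_printed_whole_site_mean(self):
        assert mean_after_removal(39, 119.4, 591.31) == pytest.approx(106.9, abs=0.5)

    def test_removing_the_mean_leaves_mean(self):
        assert mean_after_removal(10, 50.0, 50.0) == pytest.approx(50.0)

    def test_exact_arithmetic(self):
        values = [3.0, 7.0, 20.0, 30.0]
        updated = mean_after_removal(4, float(np.mean(values)), 30.0)
        assert updated == pytest.approx(np.mean(values[:-1]))

    def test_n_below_two_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            mean_after_removal(1, 5.0, 5.0)


class TestCompareZones:
    def test_identical_groups_not_significant(self):
        res = compare_zones([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        assert res.p_value == 1.0 and not res.significant

    def test_well_separated_groups_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(138.1, 82.9, 23)
        b = rng.normal(59.5, 37.7, 15)
        res = compare_zones(a, b)
        assert res.p_value < 0.001 and res.significant

    def test_permutation_agrees_in_verdict(self):
        rng = np.random.default_rng(1)
        a = rng.lognormal(4.7, 0.55, 23)
        b = rng.lognormal(3.9, 0.58, 15)
        welch = compare_zones(a, b, method="welch")
        perm = compare_zones(a, b, method="permutation", seed=0)
        assert welch.significant == perm.significant

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            compare_zones([1.0], [2.0, 3.0])


class TestIrrigationLoad:
    def test_annual_load_at_observed_water_concentration(self):
        """6.65 mg/L x 7.63 L/s x 1800 s x 104 events/yr -> 9.5 kg/yr."""
        spec = IrrigationSpec(concentration_mg_per_l=6.65)
        assert round(annual_arsenic_load(spec), 1) == 9.5

    def test_annual_load_at_nominal_six(self):
        spec = IrrigationSpec(concentration_mg_per_l=6.0)
        assert annual_arsenic_load(spec) == pytest.approx(8.57, abs=0.005)

    def test_cumulative_is_annual_times_years(self):
        spec = IrrigationSpec()
        assert cumulative_load(spec) == pytest.approx(
            annual_arsenic_load(spec) * 13.0)

    def test_zero_concentration_rejected_by_validation(self):
        with pytest.raises(ValueError, match="concentration"):
            annual_arsenic_load(IrrigationSpec(concentration_mg_per_l=0.0))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.floats(0.1, 10.0), st.sampled_from(
        ["concentration_mg_per_l", "flow_l_per_s", "duration_s",
         "events_per_week", "weeks_per_year"]))
    def test_load_linear_in_each_field(self, factor, field):
        base = IrrigationSpec()
        scaled = IrrigationSpec(**{
            **{f: getattr(base, f) for f in base.__dataclass_fields__},
            field: getattr(base, field) * factor})
        assert annual_arsenic_load(scaled) == pytest.approx(
            annual_arsenic_load(base) * factor, rel=1e-12)


class TestHelpers:
    def test_fold_exceedance_water(self):
        assert fold_exceedance(6.0, 0.4) == pytest.approx(15.0)

    def test_truncate_decimals(self):
        assert truncate_decimals(6.2772, 1) == 6.2
        assert truncate_decimals(9.99, 1) == 9.9

    def test_depth_profile_monotone_ratio(self, site, pop):
        from pitchrisk.synthetic import SoilPopulationSpec, generate_depth_cores

        quiet = SoilPopulationSpec(depth_noise_cv=0.0)
        cores = generate_depth_cores(site, quiet)
        prof = depth_profile(cores[cores["zone"] == "IA"])
        assert prof["ratio_to_surface"].iloc[0] == 1.0
        assert prof["ratio_to_surface"].is_monotonic_decreasing
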