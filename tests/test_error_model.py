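"""Stirling error curve, calibration, weighted band and the WFI."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinwfi.error_model import (
    AssumedErrorTable,
    ErrorModelParams,
    absolute_error,
    band_half_width,
    calibrate,
    error_band,
    stirling_error,
    wfi,
    wfi_report,
)
from kinwfi.simulator import TimeCourse

REF = ErrorModelParams(a=1.0, b=-9.0, k=-10.0)

@st.composite
def params_strategy(draw):
    a = draw(st.floats(0.1, 1.5))
    k = draw(st.floats(-12.0, -0.5))
    # keep the plateau a - b/k strictly positive
    b = draw(st.floats(-0.9 * a * abs(k), -0.01))
    return ErrorModelParams(a=a, b=b, k=k)


class TestStirlingCurve:
    @settings(derandomize=True, max_examples=50)
    @given(params=params_strategy())
    def test_starts_at_a(self, params):
        assert stirling_error(0.0, params) == pytest.approx(params.a, rel=1e-12)

    def test_reference_plateau_is_ten_percent(self):
        assert REF.plateau == pytest.approx(0.10, abs=1e-12)
        assert stirling_error(50.0, REF) == pytest.approx(0.10, abs=1e-12)

    def test_reference_value_at_thirty_percent_yield(self):
        # direct evaluation: 1 + 0.9*(exp(-3) - 1) = 0.144808...
        assert stirling_error(0.3, REF) == pytest.approx(0.1448084, abs=1e-6)
        # inside the assumed 15% stage value at 30% yield
        assert stirling_error(0.3, REF) < 0.15

    @settings(derandomize=True, max_examples=50)
    @given(
        params=params_strategy(),
        x1=st.floats(0.0, 0.8),
        dx=st.floats(0.01, 0.5),
    )
    def test_strictly_decreasing(self, params, x1, dx):
        assert stirling_error(x1 + dx, params) < stirling_error(x1, params)

    def test_linear_limit_when_k_is_zero(self):
        p = ErrorModelParams(a=0.5, b=-0.2, k=0.0)
        assert stirling_error(0.4, p) == pytest.approx(0.5 - 0.2 * 0.4, rel=1e-12)

    def test_negative_yield_rejected(self):
        with pytest.raises(ValueError):
            stirling_error(-0.1, REF)

    def test_positive_plateau_enforced(self):
        with pytest.raises(ValueError, match="plateau"):
            ErrorModelParams(a=1.0, b=-20.0, k=-10.0)


class TestCalibration:
    def test_self_consistency_on_exact_curve(self):
        x = np.array([0.0, 0.1, 0.3, 0.5, 1.0])
        table = AssumedErrorTable(x=x, rel_error=stirling_error(x, REF))
        result = calibrate(table)
        assert result.converged
        assert result.params.a == pytest.approx(1.0, abs=1e-6)
        assert result.params.b == pytest.approx(-9.0, abs=1e-5)
        assert result.params.k == pytest.approx(-10.0, abs=1e-5)

    def test_reference_table_fit_stays_within_assumed_ranges(self):
        """The fitted band lies inside each stage's assumed relative range."""
        table = AssumedErrorTable.reference()
        params = calibrate(table).params
        # printed stage values carry two significant figures; allow half a
        # yield point of fit slack
        for x, rel in zip(table.x[1:], table.rel_error[1:]):  # skip x=0 anchor
            lo, hi = error_band(x, params)
            assert lo >= x * (1.0 - rel) - 5e-3
            assert hi <= x * (1.0 + rel) + 5e-3

    def test_underdetermined_table_rejected(self):
        with pytest.raises(ValueError, match=">= 3 rows"):
            calibrate(AssumedErrorTable(x=[0.1, 0.5], rel_error=[0.5, 0.1]))

    def test_csv_roundtrip(self, tmp_path):
        p = tmp_path / "err.csv"
        AssumedErrorTable.reference().to_csv(p)
        back = AssumedErrorTable.from_csv(p)
        np.testing.assert_allclose(back.x, AssumedErrorTable.reference().x)


class TestErrorBand:
    def test_fifty_percent_relative_error_at_ten_percent_yield(self):
        # constant 50% relative error: expected range 5-15% at 10% yield
        flat = ErrorModelParams(a=0.5, b=0.0, k=0.0)
        assert error_band(0.10, flat) == pytest.approx((0.05, 0.15), abs=1e-12)

    def test_ten_percent_relative_error_at_fifty_percent_yield(self):
        # constant 10% relative error: expected range 45-55% at 50% yield
        flat = ErrorModelParams(a=0.1, b=0.0, k=0.0)
        assert error_band(0.50, flat) == pytest.approx((0.45, 0.55), abs=1e-12)

    def test_zero_yield_band_is_the_floor(self):
        lo, hi = error_band(0.0, REF)
        assert (lo, hi) == (0.0, REF.floor)

    def test_lower_edge_clipped_at_zero(self):
        # at 0.4% yield the floor half-width exceeds the yield itself
        lo, _ = error_band(0.004, REF)
        assert lo == 0.0

    def test_floor_dominates_tiny_yields(self):
        assert band_half_width(1e-4, REF) == REF.floor


class TestAbsoluteError:
    def test_basic_values(self):
        assert absolute_error(0.4, 0.4) == 0.0
        assert absolute_error(0.4, 0.5) == pytest.approx(0.1, rel=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(x=st.floats(0, 1), y=st.floats(0, 1))
    def test_symmetry(self, x, y):
        assert absolute_error(x, y) == absolute_error(y, x)


class TestWFI:
    ys = np.array([0.1, 0.3, 0.5, 0.9])

    def test_perfect_agreement_gives_zero(self):
        assert wfi(self.ys, self.ys, REF) == 0.0

    def test_every_point_on_band_edge_gives_exactly_one(self):
        w = band_half_width(self.ys, REF)
        assert wfi(self.ys, self.ys + w, REF) == pytest.approx(1.0, abs=1e-12)
        assert wfi(self.ys, self.ys - w, REF) == pytest.approx(1.0, abs=1e-12)

    def test_alternating_half_and_one_and_a_half_widths_average_to_one(self):
        w = band_half_width(self.ys, REF)
        signs = np.array([0.5, 1.5, 0.5, 1.5])
        assert wfi(self.ys, self.ys + signs * w, REF) == pytest.approx(1.0, abs=1e-12)

    def test_strictly_inside_band_below_one(self):
        w = band_half_width(self.ys, REF)
        assert wfi(self.ys, self.ys + 0.99 * w, REF) < 1.0

    @settings(derandomize=True, max_examples=30)
    @given(
        fracs=st.lists(st.floats(-1.0, 1.0), min_size=1, max_size=12),
    )
    def test_band_coverage_property(self, fracs):
        """Deviations within +-w always give WFI <= 1."""
        rng = np.random.default_rng(0)
        ys = rng.uniform(0.0, 1.0, size=len(fracs))
        w = band_half_width(ys, REF)
        ye = np.clip(ys + np.asarray(fracs) * w, 0.0, None)
        assert wfi(ys, ye, REF) <= 1.0 + 1e-9

    def test_increasing_a_single_deviation_never_decreases_wfi(self):
        w = band_half_width(self.ys, REF)
        ye = self.ys + 0.4 * w
        base = wfi(self.ys, ye, REF)
        ye2 = ye.copy()
        ye2[2] += 0.3 * w[2]
        assert wfi(self.ys, ye2, REF) > base

    def test_scale_consistency_fraction_vs_percent(self):
        """WFI is identical on 0-1 and 0-100 scales when floor is rescaled."""
        ye = self.ys + np.array([0.01, -0.02, 0.04, 0.01])
        pct = ErrorModelParams(a=1.0, b=-9.0 / 100, k=-10.0 / 100, floor=0.5)
        assert wfi(self.ys, ye, REF) == pytest.approx(
            wfi(self.ys * 100, ye * 100, pct), rel=1e-12
        )

    def test_low_yield_points_penalized_less_for_equal_relative_deviation(self):
        """The relative band is widest early: a 20% relative miss at 10%
        yield costs less than the same relative miss at 90% yield."""
        lo = wfi(np.array([0.1]), np.array([0.1 * 1.2]), REF)
        hi = wfi(np.array([0.9]), np.array([0.9 * 1.2]), REF)
        assert lo < hi

    def test_time_mismatch_rejected(self):
        a = TimeCourse(times_min=[1, 2], yields={"1": [0.5, 0.4]})
        b = TimeCourse(times_min=[1, 3], yields={"1": [0.5, 0.4]})
        with pytest.raises(ValueError, match="same times"):
            wfi(a, b, REF)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            wfi(np.array([]), np.array([]), REF)

    def test_t0_point_excluded_by_default(self):
        sim = TimeCourse(times_min=[0, 1, 2], yields={"1": [1.0, 0.5, 0.4]})
        exp = TimeCourse(times_min=[0, 1, 2], yields={"1": [0.7, 0.5, 0.4]})
        assert wfi(sim, exp, REF) == 0.0  # the t=0 mismatch is ignored
        assert wfi(sim, exp, REF, exclude_t0=False) > 0.0


class TestWFIReport:
    def _courses(self):
        t = [1, 2, 4]
        sim = TimeCourse(
            times_min=t,
            yields={"1": [0.8, 0.6, 0.4], "2": [0.2, 0.35, 0.5], "di-2": [0.0, 0.05, 0.1]},
        )
        return sim

    def test_identical_inputs_give_all_zeros(self):
        sim = self._courses()
        report = wfi_report({"e1": sim}, {"e1": sim}, REF)
        assert (report.table.to_numpy() == 0).all()

    def test_average_is_mean_of_species_values(self):
        sim = self._courses()
        exp = TimeCourse(
            times_min=sim.times_min,
            yields={k: v + 0.01 for k, v in sim.yields.items()},
        )
        report = wfi_report({"e1": sim}, {"e1": exp}, REF)
        row = report.table.loc["e1"]
        assert row["Ave."] == pytest.approx(
            np.mean([row["1"], row["2"], row["di-2"]]), rel=1e-12
        )

    def test_single_species_average_equals_its_wfi(self):
        t = [1, 2, 4]
        sim = TimeCourse(times_min=t, yields={"1": [0.8, 0.6, 0.4]})
        exp = TimeCourse(times_min=t, yields={"1": [0.82, 0.57, 0.44]})
        report = wfi_report({"e1": sim}, {"e1": exp}, REF)
        assert report.table.loc["e1", "Ave."] == pytest.approx(
            wfi(sim, exp, REF), rel=1e-12
        )

    def test_missing_species_excluded_from_average_with_warning(self):
        sim = self._courses()
        exp = TimeCourse(
            times_min=sim.times_min,
            yields={"1": sim.yields["1"], "2": sim.yields["2"]},
        )
        with pytest.warns(UserWarning, match="di-2"):
            report = wfi_report({"e1": sim}, {"e1": exp}, REF)
        assert np.isnan(report.table.loc["e1", "di-2"])
        assert not np.isnan(report.table.loc["e1", "Ave."])

    def test_mismatched_experiment_ids_rejected(self):
        sim = self._courses()
        with pytest.raises(ValueError, match="ids differ"):
            wfi_report({"e1": sim}, {"e2": sim}, REF)

    def test_csv_export(self, tmp_path):
        sim = self._courses()
        report = wfi_report({"e1": sim}, {"e1": sim}, REF)
        p = tmp_path / "wfi.csv"
        report.to_csv(p)
        assert "experiment_id" in p.read_text().splitlines()[0]
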