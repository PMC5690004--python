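"""Exam mA summaries, exponential percentile fits, limit derivation, rails."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ctmaster import (ExamRecord, ExtrapolationWarning, InsufficientDataError,
                      InvalidInputError, ProtocolSpec, SizeFitModel,
                      derive_ma_limits, detect_rail_events, exam_ma_distribution,
                      fit_percentile_curves, simulate_exam_population)


def _sorted_percentile(values, q):
    """Independent linear-interpolation percentile on sorted order statistics."""
    xs = sorted(values)
    if len(xs) == 1:
        return xs[0]
    pos = q / 100.0 * (len(xs) - 1)
    lo = int(math.floor(pos))
    hi = min(lo + 1, len(xs) - 1)
    frac = pos - lo
    return xs[lo] * (1 - frac) + xs[hi] * frac


class TestExamMaDistribution:
    def test_constant_list_degenerates_cleanly(self):
        st_ = exam_ma_distribution([200.0] * 20)
        assert (st_.p10_ma, st_.median_ma, st_.p90_ma) == (200.0, 200.0, 200.0)
        assert st_.whisker_low == st_.whisker_high == 200.0
        assert st_.outliers == ()

    def test_linear_interpolation_percentiles(self):
        st_ = exam_ma_distribution(list(range(1, 101)))
        assert st_.median_ma == pytest.approx(50.5)
        assert st_.p10_ma == pytest.approx(10.9)
        assert st_.p90_ma == pytest.approx(90.1)

    def test_empty_list_raises(self):
        with pytest.raises(InvalidInputError):
            exam_ma_distribution([])

    def test_outlier_rule_uses_percentile_band(self):
        values = [100.0] * 50 + [105.0] * 50 + [500.0]  # 500 is far outside
        st_ = exam_ma_distribution(values)
        assert st_.outliers == (500.0,)
        assert st_.whisker_high == 105.0

    @given(st.lists(st.floats(min_value=1.0, max_value=1000.0,
                              allow_nan=False), min_size=1, max_size=200))
    def test_percentiles_match_sort_based_oracle(self, values):
        st_ = exam_ma_distribution(values)
        assert st_.p10_ma == pytest.approx(_sorted_percentile(values, 10), rel=1e-12)
        assert st_.median_ma == pytest.approx(_sorted_percentile(values, 50), rel=1e-12)
        assert st_.p90_ma == pytest.approx(_sorted_percentile(values, 90), rel=1e-12)


class TestFitPercentileCurves:
    @staticmethod
    def _noiseless_points(a, b, sizes):
        from ctmaster import ExamStats
        return [(s, ExamStats(median_ma=a * math.exp(b * s),
                              p10_ma=0.6 * a * math.exp(b * s),
                              p90_ma=1.6 * a * math.exp(b * s),
                              whisker_low=0.5 * a * math.exp(b * s),
                              whisker_high=1.7 * a * math.exp(b * s)))
                for s in sizes]

    def test_exact_on_noiseless_exponential(self):
        points = self._noiseless_points(3.0, 0.055, np.linspace(40, 100, 13))
        fit = fit_percentile_curves(points)
        assert fit.fits["median"].a == pytest.approx(3.0, rel=1e-9)
        assert fit.fits["median"].b == pytest.approx(0.055, rel=1e-9)
        assert fit.fits["p90"].a == pytest.approx(4.8, rel=1e-9)

    def test_monotone_in_size_for_positive_b(self):
        points = self._noiseless_points(3.0, 0.055, np.linspace(40, 100, 8))
        fit = fit_percentile_curves(points)
        grid = np.linspace(40, 100, 50)
        med = [fit.evaluate("median", s) for s in grid]
        assert all(x < y for x, y in zip(med, med[1:]))

    def test_noisy_recovery_within_ten_percent(self, truth_model):
        truth = SizeFitModel.from_params(
            {"p10": (1.8, 0.055), "median": (3.0, 0.055), "p90": (5.0, 0.055)})
        records = simulate_exam_population(truth, n=200, noise_cv=0.10, seed=42)
        points = [(r.size_sum_cm, exam_ma_distribution(r.ma_values)) for r in records]
        fit = fit_percentile_curves(points)
        assert fit.fits["median"].b == pytest.approx(0.055, rel=0.10)

    def test_two_distinct_sizes_insufficient(self):
        points = self._noiseless_points(3.0, 0.055, [50.0, 60.0, 60.0])
        with pytest.raises(InsufficientDataError):
            fit_percentile_curves(points)

    def test_json_round_trip(self, truth_model, tmp_path):
        path = truth_model.save(tmp_path / "fit.json")
        back = SizeFitModel.load(path)
        assert back.fits["median"].a == truth_model.fits["median"].a
        assert back.fits["p90"].b == truth_model.fits["p90"].b


class TestDeriveMaLimits:
    @pytest.fixture()
    def fit(self):
        return SizeFitModel.from_params(
            {"p10": (1.0, 0.05), "median": (2.0, 0.052), "p90": (3.0, 0.055)},
            s_range=(40.0, 100.0))

    def test_medium_class_max_from_p90_at_upper_bound(self, fit):
        _, ma_max = derive_ma_limits(fit, "medium")
        assert ma_max == 185.0  # round5(3 * e^(0.055*75))

    def test_medium_class_min_from_p10_at_lower_bound(self, fit):
        ma_min, _ = derive_ma_limits(fit, "medium")
        assert ma_min == 15.0  # round5(1 * e^(0.05*55))

    def test_large_class_evaluates_max_at_100_cm(self, fit):
        _, ma_max = derive_ma_limits(fit, "large")
        assert ma_max == round(3.0 * math.exp(0.055 * 100.0) / 5) * 5

    def test_floor_clamps_ma_min_up(self, fit):
        ma_min, _ = derive_ma_limits(fit, "medium", ma_floor=30.0)
        assert ma_min == 30.0

    def test_extrapolation_warns(self, fit):
        with pytest.warns(ExtrapolationWarning):
            derive_ma_limits(fit, "small")  # lower bound 0 cm, 40 cm below support

    def test_min_below_max_when_curves_ordered(self, fit):
        ma_min, ma_max = derive_ma_limits(fit, "medium")
        assert ma_min < ma_max


class TestDetectRailEvents:
    @pytest.fixture()
    def protocol(self, catalog):
        return ProtocolSpec(name="p", master_id="B4", kv=120, ma_min=30, ma_max=400,
                            t=0.4, p=0.516, ni=15.5,
                            scanner=catalog.scanner("LightSpeed VCT"))

    def test_all_inside_is_zero_zero(self, protocol):
        rec = ExamRecord(ma_values=[100.0, 200.0, 300.0])
        assert detect_rail_events(rec, protocol) == (0.0, 0.0)

    def test_ceiling_fraction_counts_values_at_ma_max(self, protocol):
        rec = ExamRecord(ma_values=[400.0] * 3 + [200.0] * 27)
        ceiling, floor = detect_rail_events(rec, protocol)
        assert ceiling == pytest.approx(0.1)
        assert floor == 0.0

    def test_floor_fraction_counts_values_at_ma_min(self, protocol):
        rec = ExamRecord(ma_values=[30.0] * 6 + [200.0] * 24)
        ceiling, floor = detect_rail_events(rec, protocol)
        assert ceiling == 0.0
        assert floor == pytest.approx(0.2)

    def test_empty_record_raises(self, protocol):
        with pytest.raises(InvalidInputError):
            detect_rail_events(ExamRecord(ma_values=[]), protocol)
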