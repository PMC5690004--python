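"""The analytic core: mA scaling rules, factors, durations, option tables."""

import math

import pytest
from hypothesis import given, strategies as st

from ctmaster import (FactorSet, InvalidInputError, compute_fd, compute_fg,
                      compute_fkv, customize_protocol, dose_change_ratio,
                      enumerate_options, eq1_scale, eq2_scale, round_to_station,
                      scan_duration)

positive = st.floats(min_value=0.1, max_value=10.0, allow_nan=False)


class TestScaleRules:
    def test_within_scanner_trauma_ceiling(self):
        """Halving the noise index and lengthening rotation: 400 -> 640 mA."""
        scale = eq1_scale(0.4, 0.516, 15.5, 0.6, 0.516, 10.0)
        assert round_to_station(400.0 * scale) == 640.0

    def test_within_scanner_precontrast_ceiling(self):
        scale = eq1_scale(0.4, 0.516, 15.5, 0.4, 0.516, 22.0)
        assert round_to_station(400.0 * scale) == 200.0

    def test_identity_parameters_give_unit_scale(self):
        assert eq1_scale(0.4, 0.516, 15.5, 0.4, 0.516, 15.5) == pytest.approx(1.0)
        assert eq2_scale(0.4, 0.516, 0.4, 0.516) == pytest.approx(1.0)

    def test_cross_scanner_slower_rotation(self):
        """Same protocol on a 0.5 s platform needs 4/5 of the mA: 400 -> 320."""
        assert 400.0 * eq2_scale(0.4, 0.516, 0.5, 0.516) == pytest.approx(320.0)

    def test_cross_scanner_longer_rotation_with_denoiser_loss(self):
        scale = eq2_scale(0.4, 0.984, 0.9, 0.984, FactorSet(fd=1.25))
        assert 700.0 * scale == pytest.approx(389.0, abs=1.0)

    def test_cross_scanner_lower_pitch_with_denoiser_loss(self):
        scale = eq2_scale(0.4, 0.984, 0.4, 0.516, FactorSet(fd=1.25))
        assert 700.0 * scale == pytest.approx(458.8, abs=1.0)

    @given(positive, positive, positive, positive)
    def test_eq1_reduces_to_eq2_when_quality_unchanged(self, t1, p1, t2, p2):
        f = FactorSet(fkv=1.1, fd=0.8)
        assert eq1_scale(t1, p1, 15.5, t2, p2, 15.5, f) == pytest.approx(
            eq2_scale(t1, p1, t2, p2, f), rel=1e-12)  # FG=1 in f

    @given(positive, positive, positive, positive, positive, positive)
    def test_cross_scanner_scales_compose(self, ta, pa, tb, pb, tc, pc):
        ab = eq2_scale(ta, pa, tb, pb)
        bc = eq2_scale(tb, pb, tc, pc)
        ac = eq2_scale(ta, pa, tc, pc)
        assert ab * bc == pytest.approx(ac, rel=1e-12)

    @given(positive, positive, positive, positive,
           st.floats(min_value=50, max_value=800))
    def test_effective_mas_conserved_at_fixed_quality(self, t1, p1, t2, p2, ma):
        """mA*t/P is invariant when NI and all factors are unchanged."""
        ma_new = ma * eq1_scale(t1, p1, 15.5, t2, p2, 15.5)
        assert ma_new * t2 / p2 == pytest.approx(ma * t1 / p1, rel=1e-12)


class TestFactors:
    def test_geometry_factor_wide_bore(self):
        assert compute_fg(949.0, 1062.5) == pytest.approx(1.254, abs=5e-4)

    def test_geometry_factor_reverse(self):
        assert compute_fg(1062.5, 949.0) == pytest.approx(0.7977, abs=5e-4)

    @given(positive, positive)
    def test_geometry_factors_are_reciprocal(self, sid1, sid2):
        assert compute_fg(sid1, sid2) * compute_fg(sid2, sid1) == pytest.approx(1.0)

    @pytest.mark.parametrize("contrast, noise, expected", [
        (1.32, 2.17, 1.25),   # 100 -> 80 kV
        (1.27, 1.63, 1.01),   # 120 -> 100 kV
        (1.21, 1.39, 0.95),   # 140 -> 120 kV
        (1.0, 1.0, 1.0),
    ])
    def test_beam_energy_factor(self, contrast, noise, expected):
        assert compute_fkv(contrast, noise) == pytest.approx(expected, abs=0.005)

    def test_denoiser_factor(self):
        assert compute_fd(11.1, 13.9) == pytest.approx(0.8, abs=0.005)
        assert compute_fd(8.0, 10.0) == pytest.approx(0.8)
        assert compute_fd(5.0, 5.0) == 1.0

    def test_equal_cnr_dose_ratio(self):
        fkv = compute_fkv(1.32, 2.17)
        assert dose_change_ratio(fkv, 1.89) == pytest.approx(0.66, abs=0.005)
        assert dose_change_ratio(1.0, 1.0) == 1.0
        assert dose_change_ratio(0.95, 1.39) == pytest.approx(0.683, abs=5e-4)

    def test_factor_set_rejects_nonpositive(self):
        with pytest.raises(InvalidInputError):
            FactorSet(fkv=0.0)


class TestScanDuration:
    def test_reference_durations(self):
        assert scan_duration(0.4, 0.984, 45.0, 64, 0.625) == pytest.approx(4.6, abs=0.05)
        assert scan_duration(0.9, 0.984, 45.0, 64, 0.625) == pytest.approx(10.3, abs=0.05)

    @given(positive, positive, st.floats(min_value=10, max_value=100))
    def test_doubling_pitch_halves_duration(self, t, p, d):
        assert scan_duration(t, 2 * p, d, 64, 0.625) == pytest.approx(
            scan_duration(t, p, d, 64, 0.625) / 2, rel=1e-12)

    def test_linear_in_time_and_length(self):
        base = scan_duration(0.4, 0.984, 45.0, 64, 0.625)
        assert scan_duration(0.8, 0.984, 45.0, 64, 0.625) == pytest.approx(2 * base)
        assert scan_duration(0.4, 0.984, 90.0, 64, 0.625) == pytest.approx(2 * base)


class TestCustomizeProtocol:
    def test_routine_to_trauma_reproduces_published_range(self, routine_protocol):
        result = customize_protocol(routine_protocol,
                                    target={"t": 0.6, "ni": 10.0, "name": "trauma"},
                                    mode="within", ma_floor=50.0)
        assert result.new_protocol.ma_min == 50.0
        assert result.new_protocol.ma_max == 640.0
        assert result.feasibility.feasible

    def test_cross_scanner_slower_platform(self, catalog, routine_protocol):
        result = customize_protocol(
            routine_protocol,
            target={"t": 0.5, "scanner": catalog.scanner("Optima 660")},
            mode="cross", ma_floor=40.0)
        assert (result.new_protocol.ma_min, result.new_protocol.ma_max) == (40.0, 320.0)

    def test_no_change_customization_is_identity(self, routine_protocol):
        result = customize_protocol(routine_protocol, target={}, mode="within",
                                    ma_floor=routine_protocol.ma_min)
        assert result.scale_factor == pytest.approx(1.0)
        assert result.new_protocol.ma_min == routine_protocol.ma_min
        assert result.new_protocol.ma_max == routine_protocol.ma_max
        assert result.feasibility.feasible

    def test_round_trip_recovers_original_up_to_station(self, catalog, routine_protocol):
        """A -> B with factor f, then B -> A with 1/f, recovers the mA range."""
        f = FactorSet(fg=compute_fg(949.0, 1062.5))
        there = customize_protocol(routine_protocol,
                                   target={"t": 0.5,
                                           "scanner": catalog.scanner("Optima 580")},
                                   mode="cross", f=f, ma_floor=0.0)
        back = customize_protocol(there.new_protocol,
                                  target={"t": 0.4,
                                          "scanner": routine_protocol.scanner},
                                  mode="cross",
                                  f=FactorSet(fg=compute_fg(1062.5, 949.0)),
                                  ma_floor=0.0)
        assert back.new_protocol.ma_max == pytest.approx(routine_protocol.ma_max, abs=5.0)
        assert back.new_protocol.ma_min == pytest.approx(routine_protocol.ma_min, abs=5.0)

    def test_ceiling_violation_is_feasibility_failure_not_exception(
            self, catalog, routine_protocol):
        result = customize_protocol(
            routine_protocol,
            target={"ni": 9.0, "scanner": catalog.scanner("Optima 580")},
            mode="within")
        assert result.new_protocol.ma_max > 500.0
        assert not result.feasibility.feasible
        assert any("ceiling" in m for m in result.feasibility.messages)

    def test_ni_normalized_across_reference_thickness(self, routine_protocol):
        """NI 15.5 @5 mm equals NI 21.92 @2.5 mm: same demand, unit scale."""
        result = customize_protocol(
            routine_protocol,
            target={"ni": 15.5 * math.sqrt(2.0), "ref_thickness_mm": 2.5},
            mode="within", ma_floor=routine_protocol.ma_min)
        assert result.scale_factor == pytest.approx(1.0, rel=1e-12)


TRADEOFF_GRID = [
    {"label": "Original protocol", "kv": 100, "t": 0.4, "p": 0.984, "ni": 20},
    {"label": "Higher kV", "kv": 120, "t": 0.4, "p": 0.984, "ni": 16,
     "fkv": 0.8, "fd": 1.25},
    {"label": "Longer t", "kv": 100, "t": 0.9, "p": 0.984, "ni": 20, "fd": 1.25},
    {"label": "Lower P", "kv": 100, "t": 0.4, "p": 0.516, "ni": 20, "fd": 1.25},
    {"label": "Combination", "kv": 120, "t": 0.6, "p": 0.984, "ni": 16,
     "fkv": 0.8, "fd": 1.25},
]


def _resolver(orig, cand):
    return FactorSet(**{k: cand.get(k, 1.0) for k in ("fg", "fkv", "fd", "fss")})


class TestEnumerateOptions:
    @pytest.fixture()
    def angio(self, catalog):
        return catalog.protocol("angio abdomen medium adult")

    @pytest.fixture()
    def target(self, catalog):
        return catalog.scanner("Optima 580")  # 500 mA @ 120 kV, 400 mA @ 100 kV

    def test_tradeoff_table_feasibility_flags(self, angio, target):
        table = enumerate_options(angio, target, TRADEOFF_GRID,
                                  factor_resolver=_resolver, d_cm=45.0)
        by_label = table.set_index("label")
        assert by_label.loc["Longer t", "feasible"]
        assert by_label.loc["Combination", "feasible"]
        assert not by_label.loc["Higher kV", "feasible"]
        assert not by_label.loc["Lower P", "feasible"]
        assert by_label.loc["Longer t", "ma_max"] == pytest.approx(389.0, abs=1.0)
        assert by_label.loc["Combination", "ma_max"] == pytest.approx(467.0, abs=1.0)
        # feasible rows come first, ordered by scan duration
        assert list(table["label"][:2]) == ["Combination", "Longer t"]

    def test_duration_constraint_excludes_slow_options(self, angio, target):
        table = enumerate_options(angio, target, TRADEOFF_GRID,
                                  factor_resolver=_resolver, d_cm=45.0,
                                  max_duration_s=5.0)
        row = table.set_index("label").loc["Longer t"]
        assert not row["feasible"]
        assert "duration" in row["reason"]

    def test_identity_grid_single_feasible_row(self, routine_protocol, catalog):
        table = enumerate_options(routine_protocol,
                                  catalog.scanner("LightSpeed VCT"),
                                  [{"label": "as-is"}])
        assert len(table) == 1
        assert bool(table.loc[0, "feasible"])
        assert table.loc[0, "ma_max"] == pytest.approx(400.0)

    def test_empty_grid_raises(self, routine_protocol, catalog):
        with pytest.raises(InvalidInputError):
            enumerate_options(routine_protocol,
                              catalog.scanner("LightSpeed VCT"), [])
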