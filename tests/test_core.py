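"""Domain-model behavior: size classing, NI rescaling, validation, catalogs."""

import math

import pytest
from hypothesis import given, strategies as st

from ctmaster import (InvalidInputError, ProtocolSpec, ScannerModel, SizeClassRule,
                      classify_patient_size, fkv_for_change, load_catalog,
                      rescale_noise_index, round_to_station, save_catalog)


class TestClassifyPatientSize:
    @pytest.mark.parametrize("size, expected", [
        (50.0, "small"),
        (80.0, "large"),
        (55.0, "medium"),   # boundary values belong to the upper class
        (75.0, "large"),
        (74.999, "medium"),
        (54.999, "small"),
        (0.1, "small"),
        (500.0, "large"),
    ])
    def test_classes(self, size, expected):
        assert classify_patient_size(size) == expected

    @pytest.mark.parametrize("bad", [0.0, -5.0, math.nan, math.inf])
    def test_rejects_nonpositive_or_nonfinite(self, bad):
        with pytest.raises(InvalidInputError):
            classify_patient_size(bad)

    @given(st.floats(min_value=0.01, max_value=400.0,
                     allow_nan=False, allow_infinity=False))
    def test_total_and_unique_on_positive_sizes(self, s):
        """Every positive size falls in exactly one class."""
        rule = SizeClassRule.default()
        cls = classify_patient_size(s, rule)
        lo, hi = rule.class_bounds[cls]
        assert lo <= s < hi
        others = [c for c in rule.class_bounds if c != cls]
        assert all(not (rule.class_bounds[c][0] <= s < rule.class_bounds[c][1])
                   for c in others)


class TestRescaleNoiseIndex:
    @pytest.mark.parametrize("ni, frm, to, expected", [
        (15.5, 5.0, 5.0, 15.5),                       # identity
        (15.5, 5.0, 2.5, 15.5 * math.sqrt(2.0)),      # thinner slice -> noisier
        (16.0, 5.0, 20.0, 8.0),                       # sqrt(5/20) = 0.5
    ])
    def test_values(self, ni, frm, to, expected):
        assert rescale_noise_index(ni, frm, to) == pytest.approx(expected, rel=1e-12)

    @given(st.floats(min_value=1.0, max_value=50.0),
           st.floats(min_value=0.5, max_value=10.0),
           st.floats(min_value=0.5, max_value=10.0))
    def test_roundtrip_is_identity(self, ni, a, b):
        back = rescale_noise_index(rescale_noise_index(ni, a, b), b, a)
        assert back == pytest.approx(ni, rel=1e-12)

    def test_rejects_nonpositive_thickness(self):
        with pytest.raises(InvalidInputError):
            rescale_noise_index(15.5, 0.0, 5.0)


class TestRoundToStation:
    @pytest.mark.parametrize("ma, expected", [
        (640.7, 640.0), (198.5, 200.0), (48.0, 50.0), (14.9, 15.0),
        (12.5, 15.0), (0.0, 0.0),
    ])
    def test_snaps_to_5_ma(self, ma, expected):
        assert round_to_station(ma) == expected

    def test_custom_step(self):
        assert round_to_station(317.0, step=10.0) == 320.0


class TestValidation:
    def test_protocol_rejects_inverted_ma_range(self, catalog):
        vct = catalog.scanner("LightSpeed VCT")
        with pytest.raises(InvalidInputError):
            ProtocolSpec(name="x", master_id="B0", kv=120, ma_min=400, ma_max=400,
                         t=0.4, p=0.516, ni=15.5, scanner=vct)

    def test_protocol_rejects_kv_off_station(self, catalog):
        vct = catalog.scanner("LightSpeed VCT")
        with pytest.raises(InvalidInputError):
            ProtocolSpec(name="x", master_id="B0", kv=135, ma_min=30, ma_max=400,
                         t=0.4, p=0.516, ni=15.5, scanner=vct)

    def test_scanner_rejects_ceiling_below_floor(self):
        with pytest.raises(InvalidInputError):
            ScannerModel(model_name="bad", sid_mm=949, bore_mm=700, ma_floor=100,
                         ma_ceiling_by_kv={120: 50}, kv_stations=(120,))

    def test_size_rule_rejects_gap(self):
        with pytest.raises(InvalidInputError):
            SizeClassRule(class_bounds={"small": (0, 50), "medium": (55, 75),
                                        "large": (75, math.inf)})

    def test_size_rule_rejects_empty_interval(self):
        with pytest.raises(InvalidInputError):
            SizeClassRule(class_bounds={"small": (0, 55), "medium": (55, 55),
                                        "large": (55, math.inf)})


class TestCatalogRoundTrip:
    def test_yaml_round_trip_is_lossless(self, catalog, tmp_path):
        path = save_catalog(catalog, tmp_path / "catalog.yaml")
        back = load_catalog(path)
        assert set(back.scanners) == set(catalog.scanners)
        assert set(back.protocols) == set(catalog.protocols)
        for name, scanner in catalog.scanners.items():
            assert back.scanners[name] == scanner
        for name, proto in catalog.protocols.items():
            got = back.protocols[name]
            for fld in ("kv", "ma_min", "ma_max", "t", "p", "ni",
                        "ref_thickness_mm", "size_class", "master_id"):
                assert getattr(got, fld) == getattr(proto, fld)
            assert got.scanner.model_name == proto.scanner.model_name
        assert back.size_rule == catalog.size_rule


class TestFkvLookup:
    def test_tabulated_moves(self):
        assert fkv_for_change(100, 80) == pytest.approx(1.25, abs=0.005)
        assert fkv_for_change(120, 100) == pytest.approx(1.01, abs=0.005)
        assert fkv_for_change(140, 120) == pytest.approx(0.95, abs=0.005)

    def test_reverse_move_is_reciprocal(self):
        assert fkv_for_change(80, 100) == pytest.approx(1.0 / fkv_for_change(100, 80))

    def test_chained_move_multiplies_adjacent_steps(self):
        expected = fkv_for_change(140, 120) * fkv_for_change(120, 100)
        assert fkv_for_change(140, 100) == pytest.approx(expected, rel=1e-12)

    def test_override_wins(self):
        assert fkv_for_change(100, 120, override=0.8) == 0.8

    def test_unknown_station_raises(self):
        with pytest.raises(InvalidInputError):
            fkv_for_change(90, 80)
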