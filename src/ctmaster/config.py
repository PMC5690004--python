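"""Catalog I/O: scanner platforms, protocol sets and factor tables as YAML.

A catalog file holds the structured configuration a physics group maintains:
the scanners in the install base and the master protocols defined on them.
Round-trip read/write is lossless for every scalar field.  A small built-in
example catalog mirrors the kind of GE install base the methodology was
developed on and is used by the demo pipeline and the test-suite.

The beam-energy factor table (``DEFAULT_KV_FACTORS``) carries measured
contrast and noise ratios for the standard 140/120/100/80 kV ladder; entries
are editable/overridable because the appropriate contrast ratio depends on the
imaging task (iodinated versus non-iodinated structures).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

from .core import InvalidInputError, ProtocolSpec, ScannerModel, SizeClassRule

__all__ = [
    "KvFactorEntry",
    "DEFAULT_KV_FACTORS",
    "fkv_for_change",
    "Catalog",
    "load_catalog",
    "save_catalog",
    "example_catalog",
]


@dataclass(frozen=True)
class KvFactorEntry:
    """Measured ingredients of the beam-energy factor for one kV move.

    ``contrast_ratio`` is HU(low kV)/HU(high kV) for the contrast material of
    interest (iodine by default); ``noise_ma_factor`` is the squared ratio of
    image noise at the two stations at equal effective mAs, i.e. the mA change
    needed to hold noise constant.
    """

    contrast_ratio: float
    noise_ma_factor: float

    @property
    def fkv(self) -> float:
        """Equal-CNR mA factor for the high-to-low move: noise term / contrast^2."""
        return self.noise_ma_factor / self.contrast_ratio ** 2


#: Equal-CNR beam-energy factors for the standard GE kV ladder, keyed
#: (kv_from, kv_to) in the high-to-low direction.  Iodine contrast in a
#: 25 cm phantom; noise ratios measured in a 22 cm water phantom.
DEFAULT_KV_FACTORS: dict[tuple[int, int], KvFactorEntry] = {
    (100, 80): KvFactorEntry(1.32, 2.17),
    (120, 100): KvFactorEntry(1.27, 1.63),
    (140, 120): KvFactorEntry(1.21, 1.39),
}


def fkv_for_change(kv_from: int, kv_to: int,
                   table: dict[tuple[int, int], KvFactorEntry] | None = None,
                   override: float | None = None) -> float:
    """Beam-energy factor FkV for a kV change, from a measured factor table.

    Factors are tabulated for high-to-low moves between adjacent stations; a
    low-to-high move uses the reciprocal, and non-adjacent moves chain the
    intermediate steps multiplicatively.  ``override`` short-circuits the
    lookup for task-specific values (e.g. down-weighting iodine contrast for
    non-angiographic exams) and is never auto-derived.
    """
    if override is not None:
        if override <= 0:
            raise InvalidInputError(f"FkV override must be positive, got {override}")
        return float(override)
    table = DEFAULT_KV_FACTORS if table is None else table
    kv_from, kv_to = int(kv_from), int(kv_to)
    if kv_from == kv_to:
        return 1.0
    if (kv_from, kv_to) in table:
        return table[(kv_from, kv_to)].fkv
    if (kv_to, kv_from) in table:
        return 1.0 / table[(kv_to, kv_from)].fkv
    stations = sorted({kv for pair in table for kv in pair})
    if kv_from not in stations or kv_to not in stations:
        raise InvalidInputError(
            f"no FkV entry covers {kv_from}->{kv_to} kV (stations {stations})")
    lo, hi = sorted((kv_from, kv_to))
    idx_lo, idx_hi = stations.index(lo), stations.index(hi)
    factor = 1.0
    for i in range(idx_hi, idx_lo, -1):  # chain adjacent high->low steps
        pair = (stations[i], stations[i - 1])
        if pair not in table:
            raise InvalidInputError(f"no FkV entry for intermediate step {pair}")
        factor *= table[pair].fkv
    return factor if kv_from > kv_to else 1.0 / factor


# ---------------------------------------------------------------------------
# YAML catalog (de)serialization
# ---------------------------------------------------------------------------

@dataclass
class Catalog:
    """Scanners and protocols of an install base, plus the size-class rule."""

    scanners: dict[str, ScannerModel]
    protocols: dict[str, ProtocolSpec]
    size_rule: SizeClassRule

    def scanner(self, name: str) -> ScannerModel:
        try:
            return self.scanners[name]
        except KeyError:
            raise InvalidInputError(
                f"unknown scanner {name!r}; catalog has {sorted(self.scanners)}") from None

    def protocol(self, name: str) -> ProtocolSpec:
        try:
            return self.protocols[name]
        except KeyError:
            raise InvalidInputError(
                f"unknown protocol {name!r}; catalog has {sorted(self.protocols)}") from None


def _scanner_to_dict(s: ScannerModel) -> dict:
    d = asdict(s)
    d["kv_stations"] = list(s.kv_stations)
    d["rotation_times_s"] = list(s.rotation_times_s)
    d["pitches"] = list(s.pitches)
    return d


def _protocol_to_dict(p: ProtocolSpec) -> dict:
    d = {k: v for k, v in asdict(p).items() if k != "scanner"}
    d["scanner"] = p.scanner.model_name if p.scanner else None
    return d


def _rule_to_dict(r: SizeClassRule) -> dict:
    return {
        "class_bounds": {k: [lo, None if math.isinf(hi) else hi]
                         for k, (lo, hi) in r.class_bounds.items()},
        "eval_upper_large_cm": r.eval_upper_large_cm,
    }


def _rule_from_dict(d: dict) -> SizeClassRule:
    bounds = {k: (float(lo), math.inf if hi is None else float(hi))
              for k, (lo, hi) in d["class_bounds"].items()}
    return SizeClassRule(class_bounds=bounds,
                         eval_upper_large_cm=float(d.get("eval_upper_large_cm", 100.0)))


def save_catalog(catalog: Catalog, path: str | Path) -> Path:
    """Write a catalog to a YAML document (round-trips through load_catalog)."""
    doc = {
        "scanners": [_scanner_to_dict(s) for s in catalog.scanners.values()],
        "protocols": [_protocol_to_dict(p) for p in catalog.protocols.values()],
        "size_rule": _rule_to_dict(catalog.size_rule),
    }
    path = Path(path)
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def load_catalog(path: str | Path) -> Catalog:
    """Load a YAML catalog, validating every scanner and protocol."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or "scanners" not in doc:
        raise InvalidInputError(f"{path}: not a catalog document (missing 'scanners')")
    scanners: dict[str, ScannerModel] = {}
    for sd in doc.get("scanners", []):
        s = ScannerModel(**sd)
        scanners[s.model_name] = s
    protocols: dict[str, ProtocolSpec] = {}
    for pd in doc.get("protocols", []):
        pd = dict(pd)
        scanner_name = pd.pop("scanner", None)
        scanner = None
        if scanner_name is not None:
            if scanner_name not in scanners:
                raise InvalidInputError(
                    f"protocol {pd.get('name')!r} references unknown scanner {scanner_name!r}")
            scanner = scanners[scanner_name]
        p = ProtocolSpec(scanner=scanner, **pd)
        protocols[p.name] = p
    rule = _rule_from_dict(doc["size_rule"]) if "size_rule" in doc else SizeClassRule.default()
    return Catalog(scanners=scanners, protocols=protocols, size_rule=rule)


def example_catalog() -> Catalog:
    """A small built-in install base used by the demo pipeline and tests.

    Geometry and protocol parameters follow the published example platforms
    (64-slice 949 mm SID reference scanner, a wide-bore 1062.5 mm SID unit,
    and a 16-slice platform); mA ceilings are representative tube limits.
    """
    vct = ScannerModel(
        model_name="LightSpeed VCT", sid_mm=949.0, bore_mm=700.0, ma_floor=10.0,
        ma_ceiling_by_kv={80: 410, 100: 640, 120: 800, 140: 715},
        kv_stations=(80, 100, 120, 140),
        rotation_times_s=(0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
        pitches=(0.516, 0.984, 1.375), n_rows=64, t_elem_mm=0.625,
        has_denoiser=False)
    optima580 = ScannerModel(
        model_name="Optima 580", sid_mm=1062.5, bore_mm=800.0, ma_floor=10.0,
        ma_ceiling_by_kv={80: 300, 100: 400, 120: 500, 140: 600},
        kv_stations=(80, 100, 120, 140),
        rotation_times_s=(0.5, 0.6, 0.8, 1.0),
        pitches=(0.516, 0.984, 1.375), n_rows=64, t_elem_mm=0.625,
        has_denoiser=False)
    optima660 = ScannerModel(
        model_name="Optima 660", sid_mm=949.0, bore_mm=700.0, ma_floor=10.0,
        ma_ceiling_by_kv={80: 410, 100: 640, 120: 800, 140: 715},
        kv_stations=(80, 100, 120, 140),
        rotation_times_s=(0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
        pitches=(0.516, 0.984, 1.375), n_rows=64, t_elem_mm=0.625,
        has_denoiser=True)
    hd750 = ScannerModel(
        model_name="Discovery HD 750", sid_mm=949.0, bore_mm=700.0, ma_floor=10.0,
        ma_ceiling_by_kv={80: 500, 100: 715, 120: 800, 140: 800},
        kv_stations=(80, 100, 120, 140),
        rotation_times_s=(0.4, 0.5, 0.6, 0.8, 1.0),
        pitches=(0.516, 0.984, 1.375), n_rows=64, t_elem_mm=0.625,
        has_denoiser=True,
        ni_reference_note=("Manufacturer reports a changed AEC calibration on this model; "
                           "an NI of 18 behaves like 15.5 on the reference platform for "
                           "medium adults."))
    ls16 = ScannerModel(
        model_name="LightSpeed 16", sid_mm=949.0, bore_mm=700.0, ma_floor=10.0,
        ma_ceiling_by_kv={80: 335, 100: 420, 120: 440, 140: 440},
        kv_stations=(80, 100, 120, 140),
        rotation_times_s=(0.5, 0.6, 0.8, 1.0),
        pitches=(0.562, 0.938, 1.375), n_rows=16, t_elem_mm=0.625,
        has_denoiser=False)

    protocols = [
        ProtocolSpec(name="routine abdomen-pelvis medium adult", master_id="B4",
                     kv=120, ma_min=30, ma_max=400, t=0.4, p=0.516, ni=15.5,
                     scan_length_cm=45.0, size_class="medium", scanner=vct),
        ProtocolSpec(name="trauma abdomen-pelvis medium adult", master_id="B1",
                     kv=120, ma_min=50, ma_max=640, t=0.6, p=0.516, ni=10.0,
                     scan_length_cm=45.0, size_class="medium", scanner=vct),
        ProtocolSpec(name="precontrast abdomen-pelvis medium adult", master_id="B7",
                     kv=120, ma_min=15, ma_max=200, t=0.4, p=0.516, ni=22.0,
                     scan_length_cm=45.0, size_class="medium", scanner=vct),
        ProtocolSpec(name="angio abdomen medium adult", master_id="B8",
                     kv=100, ma_min=30, ma_max=700, t=0.4, p=0.984, ni=20.0,
                     scan_length_cm=45.0, size_class="medium", scanner=hd750),
    ]
    return Catalog(scanners={s.model_name: s
                             for s in (vct, optima580, optima660, hd750, ls16)},
                   protocols={p.name: p for p in protocols},
                   size_rule=SizeClassRule.default())
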