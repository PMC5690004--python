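"""Domain model shared by every stage of the protocol-management pipeline.

CT automatic exposure control (AEC) modulates the tube current (mA) along the
patient to deliver a requested image-quality level, but every scanner is bound
by hard mA limits imposed by its X-ray tube.  A protocol is "healthy" when the
AEC never hits those rails for any patient in the protocol's size range.  This
module holds the vocabulary the rest of the package speaks: scanner platforms
and their output envelopes, protocol acquisition parameters, and the patient
size classes (AP+LAT, cm) used to split adult body protocols.

Unit conventions, fixed package-wide and converted only at I/O boundaries:
patient sizes in cm, source-to-image distance (SID) in mm, rotation times in
seconds, tube currents in mA, noise index (NI) in HU at a stated reference
slice thickness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "SIZE_CLASSES",
    "InvalidInputError",
    "ScannerModel",
    "ProtocolSpec",
    "SizeClassRule",
    "classify_patient_size",
    "rescale_noise_index",
    "round_to_station",
]

#: Ordered patient-size classes used to split adult body protocols.
SIZE_CLASSES = ("small", "medium", "large")


class InvalidInputError(ValueError):
    """Raised when an operation receives a non-physical or malformed argument."""


def _require_positive(**named: float) -> None:
    for name, value in named.items():
        if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
            raise InvalidInputError(f"{name} must be a positive finite number, got {value!r}")


def round_to_station(ma: float, step: float = 5.0) -> float:
    """Snap a tube current to the nearest selectable mA station.

    Scanner consoles expose mA in discrete steps (5 mA on the GE platforms this
    package models), so derived limits are snapped before being written into a
    protocol.  Exact halves round up.

    Parameters
    ----------
    ma : float
        Tube current in mA.
    step : float, optional
        Station spacing in mA (default 5).

    Returns
    -------
    float
        ``ma`` rounded to the nearest multiple of ``step``.
    """
    _require_positive(step=step)
    if not math.isfinite(ma):
        raise InvalidInputError(f"ma must be finite, got {ma!r}")
    return float(math.floor(ma / step + 0.5) * step)


@dataclass(frozen=True)
class ScannerModel:
    """A scanner platform's geometry and tube-output envelope.

    Attributes
    ----------
    model_name : str
        Platform name, e.g. ``"LightSpeed VCT"``.
    sid_mm : float
        Source-to-image (detector) distance in mm; drives the geometry factor
        FG through inverse-square dose fall-off at the detector.
    bore_mm : float
        Bore diameter in mm (descriptive).
    ma_floor : float
        Minimum selectable tube current in mA (scanner-wide).
    ma_ceiling_by_kv : dict[int, float]
        Maximum deliverable mA per kV station.  Tube power limits make the
        ceiling kV-dependent.
    kv_stations : tuple[int, ...]
        Selectable beam energies in kV.
    rotation_times_s : tuple[float, ...]
        Selectable gantry rotation times in seconds.
    pitches : tuple[float, ...]
        Selectable pitch values (dimensionless).
    n_rows : int
        Number of detector rows used in a scan.
    t_elem_mm : float
        Detector element z-thickness referenced to isocenter, in mm.
    has_denoiser : bool
        Whether an iterative denoising option is installed (feeds FD defaults).
    ni_reference_note : str
        Free-text remark, e.g. a manufacturer AEC-equivalence note for a
        platform whose noise-index calibration differs.  Never computed on.
    """

    model_name: str
    sid_mm: float
    bore_mm: float
    ma_floor: float
    ma_ceiling_by_kv: dict[int, float]
    kv_stations: tuple[int, ...]
    rotation_times_s: tuple[float, ...] = ()
    pitches: tuple[float, ...] = ()
    n_rows: int = 64
    t_elem_mm: float = 0.625
    has_denoiser: bool = False
    ni_reference_note: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "kv_stations", tuple(self.kv_stations))
        object.__setattr__(self, "rotation_times_s", tuple(self.rotation_times_s))
        object.__setattr__(self, "pitches", tuple(self.pitches))
        object.__setattr__(self, "ma_ceiling_by_kv",
                           {int(k): float(v) for k, v in self.ma_ceiling_by_kv.items()})
        _require_positive(sid_mm=self.sid_mm, bore_mm=self.bore_mm, t_elem_mm=self.t_elem_mm)
        if self.ma_floor < 0:
            raise InvalidInputError(f"ma_floor must be >= 0, got {self.ma_floor}")
        if self.n_rows < 1:
            raise InvalidInputError(f"n_rows must be >= 1, got {self.n_rows}")
        for kv, ceiling in self.ma_ceiling_by_kv.items():
            if ceiling <= self.ma_floor:
                raise InvalidInputError(
                    f"mA ceiling at {kv} kV ({ceiling}) must exceed the floor ({self.ma_floor})")
            if kv not in self.kv_stations:
                raise InvalidInputError(
                    f"ceiling given for {kv} kV which is not a kV station of {self.model_name}")

    def ma_ceiling(self, kv: int) -> float:
        """Maximum deliverable mA at a kV station; raises if the station is unknown."""
        try:
            return self.ma_ceiling_by_kv[int(kv)]
        except KeyError:
            raise InvalidInputError(
                f"{self.model_name} has no mA ceiling defined at {kv} kV") from None


@dataclass
class ProtocolSpec:
    """Acquisition parameters of one protocol (one quality tier, one size class).

    ``ni`` is the AEC noise index in HU quoted at ``ref_thickness_mm`` and is
    always a pre-denoising value; denoiser effects enter only through the FD
    customization factor, never by silently editing NI.
    """

    name: str
    master_id: str
    kv: int
    ma_min: float
    ma_max: float
    t: float
    p: float
    ni: float
    ref_thickness_mm: float = 5.0
    scan_length_cm: float | None = None
    size_class: str = "medium"
    scanner: ScannerModel | None = None

    def __post_init__(self) -> None:
        _require_positive(ma_min=self.ma_min, t=self.t, p=self.p, ni=self.ni,
                          ref_thickness_mm=self.ref_thickness_mm)
        if not self.ma_min < self.ma_max:
            raise InvalidInputError(
                f"ma_min ({self.ma_min}) must be strictly below ma_max ({self.ma_max})")
        if self.scan_length_cm is not None:
            _require_positive(scan_length_cm=self.scan_length_cm)
        if self.size_class not in SIZE_CLASSES:
            raise InvalidInputError(
                f"size_class must be one of {SIZE_CLASSES}, got {self.size_class!r}")
        if self.scanner is not None and int(self.kv) not in self.scanner.kv_stations:
            raise InvalidInputError(
                f"{self.kv} kV is not a station of scanner {self.scanner.model_name} "
                f"(stations: {self.scanner.kv_stations})")

    def ni_at(self, thickness_mm: float) -> float:
        """Noise index rescaled to another reference slice thickness."""
        return rescale_noise_index(self.ni, self.ref_thickness_mm, thickness_mm)

    def with_changes(self, **changes) -> "ProtocolSpec":
        """Copy with selected fields replaced (re-validated)."""
        return replace(self, **changes)


@dataclass(frozen=True)
class SizeClassRule:
    """Patient size classes as half-open AP+LAT intervals ``[lo, hi)`` in cm.

    The default splits adults at 55 and 75 cm (small / medium / large).  Exact
    boundary values belong to the upper class: 55 cm is medium, 75 cm is large.
    ``eval_upper_large_cm`` is the size at which the large class's mA ceiling
    is evaluated, since the large interval is unbounded; 100 cm is the
    conventional choice for adult abdomens.
    """

    class_bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"small": (0.0, 55.0),
                                 "medium": (55.0, 75.0),
                                 "large": (75.0, math.inf)})
    eval_upper_large_cm: float = 100.0

    def __post_init__(self) -> None:
        if tuple(self.class_bounds) != SIZE_CLASSES:
            raise InvalidInputError(
                f"class_bounds must define exactly {SIZE_CLASSES} in order, "
                f"got {tuple(self.class_bounds)}")
        prev_hi = None
        for name in SIZE_CLASSES:
            lo, hi = self.class_bounds[name]
            if not lo < hi:
                raise InvalidInputError(f"empty interval for {name}: [{lo}, {hi})")
            if prev_hi is not None and lo != prev_hi:
                raise InvalidInputError(
                    f"size intervals must be contiguous; {name} starts at {lo} "
                    f"but previous class ends at {prev_hi}")
            prev_hi = hi
        _require_positive(eval_upper_large_cm=self.eval_upper_large_cm)

    @classmethod
    def default(cls) -> "SizeClassRule":
        return cls()

    def lower(self, size_class: str) -> float:
        """Lower bound of a class interval in cm."""
        return self.class_bounds[size_class][0]

    def upper(self, size_class: str) -> float:
        """Upper bound of a class interval in cm (inf for the largest class)."""
        return self.class_bounds[size_class][1]

    def eval_size_for_max(self, size_class: str) -> float:
        """Size (cm) at which a class's maximum mA is evaluated.

        The class's upper bound, except for the unbounded large class where
        ``eval_upper_large_cm`` is used.
        """
        hi = self.upper(size_class)
        return self.eval_upper_large_cm if math.isinf(hi) else hi


def classify_patient_size(s: float, rule: SizeClassRule | None = None) -> str:
    """Assign an AP+LAT size (cm) to its patient size class.

    Total on ``(0, inf)``; exactly one class contains any positive size under
    the half-open ``[lo, hi)`` convention.

    Parameters
    ----------
    s : float
        AP+LAT size in cm (sum of anterior-posterior and lateral widths).
    rule : SizeClassRule, optional
        Class boundaries; institutional defaults when omitted.
    """
    rule = rule or SizeClassRule.default()
    _require_positive(s=s)
    for name in SIZE_CLASSES:
        lo, hi = rule.class_bounds[name]
        if lo <= s < hi:
            return name
    # The smallest class starts at 0 in the default rule; a custom rule may
    # leave a gap below its first interval.
    raise InvalidInputError(f"size {s} cm is below the smallest class interval")


def rescale_noise_index(ni: float, thickness_from: float, thickness_to: float) -> float:
    """Rescale a noise index (HU) between reference slice thicknesses.

    Quantum noise in a CT image scales as ``1/sqrt(thickness)``, so an NI
    quoted at ``thickness_from`` corresponds to
    ``ni * sqrt(thickness_from / thickness_to)`` at ``thickness_to``.
    The operation is an involution: rescaling there and back is the identity.
    """
    _require_positive(ni=ni, thickness_from=thickness_from, thickness_to=thickness_to)
    return ni * math.sqrt(thickness_from / thickness_to)
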