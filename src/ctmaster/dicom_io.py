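"""Read exam context and per-image tube current from DICOM; tabular exam I/O.

The mA demand data this package models comes straight out of clinical image
headers: every axial CT image records the average tube current used for its
rotation.  ``read_exam_headers`` turns one series into an :class:`ExamRecord`
whose ``ma_values`` are ordered along z, keeping only original
(non-reformatted, non-derived) images.  Localizer radiographs are read with
their pixel spacing so patient size can be measured downstream.

Exam tables are plain CSV with the per-image mA list JSON-encoded in one
column, one row per exam — big enough for thousands of exams, diffable, and
lossless.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import pydicom

from .core import InvalidInputError

__all__ = [
    "ExamRecord",
    "LocalizerImage",
    "EmptySeriesError",
    "MissingPixelSpacingError",
    "read_exam_headers",
    "read_localizer",
    "write_exam_table",
    "read_exam_table",
]


class EmptySeriesError(InvalidInputError):
    """No usable axial image was found in a series."""


class MissingPixelSpacingError(InvalidInputError):
    """A localizer has no pixel spacing, so no size can be measured from it."""


@dataclass
class ExamRecord:
    """One patient exam: per-image tube currents plus acquisition context.

    ``ma_values`` holds the scanner-reported average mA of each original axial
    image, ordered by slice position along z.  Sizes are in cm;
    ``size_sum_cm`` is the AP+LAT metric used for size classing and fitting.
    """

    accession: str = ""
    protocol_name: str = ""
    scanner_model: str = ""
    kv: float | None = None
    rotation_time_s: float | None = None
    pitch: float | None = None
    ma_values: list[float] = field(default_factory=list)
    size_ap_cm: float | None = None
    size_lat_cm: float | None = None
    size_sum_cm: float | None = None

    def __post_init__(self) -> None:
        self.ma_values = [float(v) for v in self.ma_values]
        for v in self.ma_values:
            if not (math.isfinite(v) and v >= 0):
                raise InvalidInputError(f"mA values must be finite and >= 0, got {v}")


@dataclass
class LocalizerImage:
    """Localizer radiograph pixel data with spacing and view classification.

    ``view`` is one of ``"AP"``, ``"PA"``, ``"frontal"`` (frontal but the
    exact direction is unknown), ``"lateral"`` or ``"unknown"``.  Rows run
    along the patient z axis, columns across the patient.
    """

    pixels: np.ndarray
    row_spacing_mm: float
    col_spacing_mm: float
    view: str = "unknown"

    @property
    def is_frontal(self) -> bool:
        return self.view in ("AP", "PA", "frontal")


def _is_original(ds: pydicom.Dataset) -> bool:
    image_type = ds.get("ImageType")
    if image_type is None:
        return True  # benefit of the doubt for minimal headers
    values = [str(v).upper() for v in image_type]
    if "LOCALIZER" in values:
        return False
    return "ORIGINAL" in values


def _tube_current(ds: pydicom.Dataset) -> float | None:
    # Prefer the floating-point attribute when present; fall back to the
    # classic integer-string one.
    if "XRayTubeCurrentInmA" in ds:
        return float(ds.XRayTubeCurrentInmA)
    if "XRayTubeCurrent" in ds:
        return float(ds.XRayTubeCurrent)
    return None


def _z_position(ds: pydicom.Dataset) -> float:
    if "ImagePositionPatient" in ds and len(ds.ImagePositionPatient) == 3:
        return float(ds.ImagePositionPatient[2])
    if "SliceLocation" in ds:
        return float(ds.SliceLocation)
    return float(ds.get("InstanceNumber", 0))


def read_exam_headers(series_paths) -> ExamRecord:
    """Build an :class:`ExamRecord` from the headers of one axial series.

    Parameters
    ----------
    series_paths : iterable of path, or a directory path
        DICOM files of a single axial series (any order; ordering is taken
        from spatial position, not file names).

    Returns
    -------
    ExamRecord
        With ``ma_values`` sorted by z.  Files without a tube-current
        attribute, and reformatted/derived/localizer images, are excluded
        with a warning.

    Raises
    ------
    EmptySeriesError
        If no usable file remains.
    """
    if isinstance(series_paths, (str, Path)) and Path(series_paths).is_dir():
        series_paths = sorted(Path(series_paths).iterdir())
    paths = [Path(p) for p in series_paths]
    kept: list[tuple[float, float]] = []
    context_ds = None
    for path in paths:
        try:
            ds = pydicom.dcmread(path, stop_before_pixels=True)
        except Exception as exc:  # unreadable file: warn and move on
            warnings.warn(f"{path.name}: unreadable DICOM ({exc}); excluded")
            continue
        if not _is_original(ds):
            warnings.warn(f"{path.name}: not an original axial image; excluded")
            continue
        ma = _tube_current(ds)
        if ma is None:
            warnings.warn(f"{path.name}: no tube-current attribute; excluded")
            continue
        kept.append((_z_position(ds), ma))
        if context_ds is None:
            context_ds = ds
    if not kept:
        raise EmptySeriesError(f"no usable axial images among {len(paths)} file(s)")
    kept.sort(key=lambda zm: zm[0])
    ds = context_ds
    rotation = float(ds.RevolutionTime) if "RevolutionTime" in ds else None
    pitch = float(ds.SpiralPitchFactor) if "SpiralPitchFactor" in ds else None
    return ExamRecord(
        accession=str(ds.get("AccessionNumber", "")),
        protocol_name=str(ds.get("ProtocolName", "")),
        scanner_model=str(ds.get("ManufacturerModelName", "")),
        kv=float(ds.KVP) if "KVP" in ds else None,
        rotation_time_s=rotation,
        pitch=pitch,
        ma_values=[ma for _z, ma in kept],
    )


_FRONTAL_VIEWS = {"AP", "PA"}
_LATERAL_VIEWS = {"LL", "RL", "L", "LAT", "LATERAL"}


def _classify_view(ds: pydicom.Dataset) -> str:
    vp = str(ds.get("ViewPosition", "")).strip().upper()
    if vp in _FRONTAL_VIEWS:
        return vp
    if vp in _LATERAL_VIEWS:
        return "lateral"
    iop = ds.get("ImageOrientationPatient")
    if iop is not None and len(iop) == 6:
        row = np.asarray([float(v) for v in iop[:3]])
        if abs(row[0]) > 0.9:      # columns run along patient x -> coronal view
            return "frontal"
        if abs(row[1]) > 0.9:      # columns run along patient y -> sagittal view
            return "lateral"
    return "unknown"


def read_localizer(path: str | Path) -> LocalizerImage:
    """Read a localizer radiograph: pixels, spacing (mm/px) and view label.

    Raises :class:`MissingPixelSpacingError` when the header carries no pixel
    spacing, since no physical width can be computed from such an image.
    """
    ds = pydicom.dcmread(path)
    spacing = ds.get("PixelSpacing") or ds.get("ImagerPixelSpacing")
    if spacing is None or len(spacing) != 2:
        raise MissingPixelSpacingError(f"{path}: localizer has no pixel spacing")
    pixels = ds.pixel_array.astype(np.float64)
    slope = float(ds.get("RescaleSlope", 1.0))
    intercept = float(ds.get("RescaleIntercept", 0.0))
    if (slope, intercept) != (1.0, 0.0):
        pixels = pixels * slope + intercept
    return LocalizerImage(
        pixels=pixels,
        row_spacing_mm=float(spacing[0]),
        col_spacing_mm=float(spacing[1]),
        view=_classify_view(ds),
    )


# ---------------------------------------------------------------------------
# Tabular exam I/O (CSV; ma_values JSON-encoded inline)
# ---------------------------------------------------------------------------

_SCALAR_COLUMNS = ["accession", "protocol_name", "scanner_model", "kv",
                   "rotation_time_s", "pitch", "size_ap_cm", "size_lat_cm",
                   "size_sum_cm"]


def write_exam_table(records: list[ExamRecord], path: str | Path) -> Path:
    """Write exam records to CSV, one row per exam.

    Scalar fields are plain columns; ``ma_values`` is JSON-encoded so the
    round trip through :func:`read_exam_table` is lossless.  Summary columns
    (n_images, median mA) are added for quick inspection and ignored on read.
    """
    rows = []
    for rec in records:
        row = {k: getattr(rec, k) for k in _SCALAR_COLUMNS}
        row["n_images"] = len(rec.ma_values)
        row["ma_median"] = float(np.median(rec.ma_values)) if rec.ma_values else None
        row["ma_values"] = json.dumps(rec.ma_values)
        rows.append(row)
    df = pd.DataFrame(rows, columns=_SCALAR_COLUMNS + ["n_images", "ma_median", "ma_values"])
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_exam_table(path: str | Path) -> list[ExamRecord]:
    """Read exam records written by :func:`write_exam_table`.

    Malformed rows raise with the offending row index in the message.
    """
    df = pd.read_csv(path)
    records = []
    for i, row in df.iterrows():
        try:
            ma_values = json.loads(row["ma_values"]) if isinstance(row["ma_values"], str) else []
            kwargs = {}
            for col in _SCALAR_COLUMNS:
                val = row.get(col)
                if col in ("accession", "protocol_name", "scanner_model"):
                    kwargs[col] = "" if pd.isna(val) else str(val)
                else:
                    kwargs[col] = None if pd.isna(val) else float(val)
            records.append(ExamRecord(ma_values=ma_values, **kwargs))
        except (ValueError, TypeError, json.JSONDecodeError) as exc:
            raise InvalidInputError(f"{path}: row {i}: {exc}") from exc
    return records
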