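"""Deterministic synthetic fixtures: localizer phantoms, DICOM series, exams.

No clinical data ships with this package; every pipeline stage is exercised
against generators whose ground truth is known by construction.

* :func:`make_localizer` renders frontal and lateral localizer radiographs of
  an elliptical-torso phantom on an optional couch.  The body silhouette has
  a steep intensity shoulder so its geometric extent — the generator's ground
  truth — is exactly what the 30%-threshold measurement should recover.  The
  couch is a low-intensity band (20% of body intensity by default) that the
  relative threshold must reject.
* :func:`simulate_exam_population` draws exam mA distributions whose
  10th/median/90th percentiles follow ``a * exp(b * s)`` truth curves with
  multiplicative lognormal noise, optionally clipped to a protocol's mA
  range so rail events emerge for the largest patients.
* :func:`make_dicom_fixture` and :func:`write_localizer_dicom` emit minimal
  standard-conformant DICOM files that round-trip through
  :mod:`ctmaster.dicom_io`.

All generators are pure functions of their arguments (including the seed):
same inputs, bit-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

from .core import InvalidInputError, ProtocolSpec
from .dicom_io import ExamRecord
from .ma_stats import SizeFitModel

__all__ = [
    "LocalizerPhantom",
    "make_localizer",
    "simulate_exam_population",
    "make_dicom_fixture",
    "write_localizer_dicom",
    "write_demo_dataset",
]

_Z90 = 1.2815515655446004  # standard normal 90th percentile


@dataclass
class LocalizerPhantom:
    """A matched frontal/lateral localizer pair with its ground truth.

    The frontal (AP/PA) view projects the patient's *lateral* width; the
    lateral view projects the *anterior-posterior* width.
    """

    frontal: np.ndarray
    lateral: np.ndarray
    pixel_spacing_mm: float
    ap_cm: float
    lat_cm: float

    def truth(self) -> dict:
        return {"ap_cm": self.ap_cm, "lat_cm": self.lat_cm,
                "size_sum_cm": self.ap_cm + self.lat_cm}


def _body_profile(width_cm: float, spacing_mm: float, fov_cm: float,
                  body_value: float, edge_sharpness: float) -> np.ndarray:
    ncols = int(round(fov_cm * 10.0 / spacing_mm))
    x = (np.arange(ncols) - (ncols - 1) / 2) * spacing_mm / 10.0  # cm from midline
    half = width_cm / 2.0
    u = np.clip(1.0 - (x / half) ** 2, 0.0, None)
    # Steep elliptical shoulder: full intensity except within a thin edge
    # zone, so the supra-threshold extent equals the geometric extent to
    # well under a pixel.
    return body_value * np.clip(edge_sharpness * np.sqrt(u), 0.0, 1.0)


def make_localizer(ap_cm: float, lat_cm: float, pixel_spacing_mm: float = 1.0,
                   couch: bool = False, noise_sd: float = 0.0, seed: int = 0, *,
                   couch_intensity_frac: float = 0.2, z_length_cm: float = 40.0,
                   body_value: float = 1000.0, edge_sharpness: float = 5.0,
                   margin_cm: float = 14.0) -> LocalizerPhantom:
    """Render the two localizer views of an elliptical torso phantom.

    Parameters
    ----------
    ap_cm, lat_cm : float
        True anterior-posterior and lateral extents, each within 10-60 cm.
    pixel_spacing_mm : float
        Isotropic pixel spacing of both views.
    couch : bool
        Add a couch at ``couch_intensity_frac`` of the body intensity: a
        uniform under-patient contribution in the frontal view, a posterior
        side band in the lateral view.
    noise_sd : float
        Additive Gaussian noise standard deviation (intensity units).
    seed : int
        Seed for the noise stream; the phantom is bit-reproducible.
    """
    for name, v in (("ap_cm", ap_cm), ("lat_cm", lat_cm)):
        if not 10.0 <= v <= 60.0:
            raise InvalidInputError(f"{name} must be within 10-60 cm, got {v}")
    if pixel_spacing_mm <= 0:
        raise InvalidInputError(f"pixel spacing must be positive, got {pixel_spacing_mm}")
    rng = np.random.default_rng(seed)
    n_rows = int(round(z_length_cm * 10.0 / pixel_spacing_mm))

    def render(width_cm: float, couch_mode: str) -> np.ndarray:
        fov_cm = width_cm + margin_cm
        profile = _body_profile(width_cm, pixel_spacing_mm, fov_cm,
                                body_value, edge_sharpness)
        img = np.tile(profile, (n_rows, 1))
        if couch:
            couch_value = couch_intensity_frac * body_value
            if couch_mode == "under":
                img = img + couch_value  # couch superimposed on the whole FOV
            else:  # posterior band beside the body in the lateral view
                ncols = img.shape[1]
                x = (np.arange(ncols) - (ncols - 1) / 2) * pixel_spacing_mm / 10.0
                band = (x >= width_cm / 2 + 0.5) & (x <= width_cm / 2 + 6.5)
                img[:, band] += couch_value
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, img.shape)
        return np.clip(img, 0.0, None)

    frontal = render(lat_cm, "under")
    lateral = render(ap_cm, "band")
    return LocalizerPhantom(frontal=frontal, lateral=lateral,
                            pixel_spacing_mm=pixel_spacing_mm,
                            ap_cm=float(ap_cm), lat_cm=float(lat_cm))


def simulate_exam_population(truth: SizeFitModel,
                             size_distribution: tuple[float, float, tuple[float, float]]
                             = (62.0, 10.0, (40.0, 100.0)),
                             n: int = 200,
                             noise_cv: float = 0.10,
                             protocol: ProtocolSpec | None = None,
                             seed: int = 0, *,
                             n_images: int = 40) -> list[ExamRecord]:
    """Simulate an exam population whose mA statistics follow truth curves.

    Per exam, a patient size ``s`` is drawn from a truncated normal, the
    whole exam is scaled by a lognormal factor of coefficient of variation
    ``noise_cv`` (exam-to-exam scatter about the curves), and per-image mA
    values are drawn lognormally around the truth median curve with a
    within-exam spread matched to the truth p90/median ratio.  When a
    protocol is supplied the values are clipped to its ``[ma_min, ma_max]``
    range, so rail events emerge for sizes whose demand exceeds the range.

    Parameters
    ----------
    truth : SizeFitModel
        Ground-truth ``a * exp(b * s)`` curves; must include ``median``, and
        uses ``p90`` for the within-exam spread when present.
    size_distribution : (mean, sd, (lo, hi))
        Truncated-normal patient-size distribution in cm.
    n : int
        Number of exams (>= 1).
    noise_cv : float
        Coefficient of variation of the exam-level multiplicative noise.
    protocol : ProtocolSpec, optional
        Supplies the mA clipping range and the acquisition context fields.
    seed : int
        Seed; one generator per call, no global state.
    n_images : int
        Images per exam.
    """
    if n < 1:
        raise InvalidInputError(f"n must be >= 1, got {n}")
    if noise_cv < 0:
        raise InvalidInputError(f"noise_cv must be >= 0, got {noise_cv}")
    mean_s, sd_s, (lo_s, hi_s) = size_distribution
    if not lo_s < hi_s:
        raise InvalidInputError(f"empty size range ({lo_s}, {hi_s})")
    rng = np.random.default_rng(seed)
    sizes = np.clip(rng.normal(mean_s, sd_s, size=n), lo_s, hi_s)
    sigma_exam = math.sqrt(math.log(1.0 + noise_cv ** 2))
    records = []
    for i, s in enumerate(sizes):
        med = truth.evaluate("median", float(s))
        if "p90" in truth.fits:
            ratio = truth.evaluate("p90", float(s)) / med
            if ratio <= 1.0:
                raise InvalidInputError("truth p90 curve must lie above the median curve")
            sigma_within = math.log(ratio) / _Z90
        else:
            sigma_within = 0.25
        exam_factor = math.exp(rng.normal(0.0, sigma_exam)) if sigma_exam > 0 else 1.0
        ma = med * exam_factor * np.exp(sigma_within * rng.standard_normal(n_images))
        if protocol is not None:
            ma = np.clip(ma, protocol.ma_min, protocol.ma_max)
        records.append(ExamRecord(
            accession=f"SYN{i:05d}",
            protocol_name=protocol.name if protocol else "synthetic abdomen-pelvis",
            scanner_model=(protocol.scanner.model_name
                           if protocol and protocol.scanner else "synthetic"),
            kv=float(protocol.kv) if protocol else 120.0,
            rotation_time_s=protocol.t if protocol else 0.4,
            pitch=protocol.p if protocol else 0.516,
            ma_values=[float(v) for v in ma],
            size_ap_cm=0.45 * float(s), size_lat_cm=0.55 * float(s),
            size_sum_cm=float(s)))
    return records


# ---------------------------------------------------------------------------
# DICOM fixture writers
# ---------------------------------------------------------------------------

def _deterministic_uid(*parts) -> str:
    return generate_uid(entropy_srcs=[str(p) for p in parts])


def _base_dataset(sop_instance_uid: str) -> Dataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = CTImageStorage
    meta.MediaStorageSOPInstanceUID = sop_instance_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = CTImageStorage
    ds.SOPInstanceUID = sop_instance_uid
    ds.Modality = "CT"
    ds.PatientName = "Synthetic^Phantom"
    ds.PatientID = "SYNTH"
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    return ds


def _set_pixels(ds: Dataset, array: np.ndarray) -> None:
    arr = np.clip(np.round(array), 0, 65535).astype(np.uint16)
    ds.Rows, ds.Columns = arr.shape
    ds.PixelData = arr.tobytes()


def make_dicom_fixture(record: ExamRecord, out_dir: str | Path, *,
                       slice_spacing_mm: float = 5.0,
                       shuffle_names_seed: int | None = None) -> list[Path]:
    """Write a minimal axial DICOM series whose headers carry the record.

    Per-image tube current is stored both as the floating-point attribute
    (read back exactly) and the classic integer one.  File names can be
    permuted (``shuffle_names_seed``) to exercise order-independent parsing;
    spatial ordering always comes from the image positions.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n = len(record.ma_values)
    if n == 0:
        raise InvalidInputError("record has no mA values to write")
    study_uid = _deterministic_uid("study", record.accession)
    series_uid = _deterministic_uid("series", record.accession)
    name_order = np.arange(n)
    if shuffle_names_seed is not None:
        name_order = np.random.default_rng(shuffle_names_seed).permutation(n)
    paths = []
    pixels = np.zeros((8, 8))
    for i, ma in enumerate(record.ma_values):
        ds = _base_dataset(_deterministic_uid("image", record.accession, i))
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.AccessionNumber = record.accession
        ds.ProtocolName = record.protocol_name
        ds.ManufacturerModelName = record.scanner_model
        ds.ImageType = ["ORIGINAL", "PRIMARY", "AXIAL"]
        ds.InstanceNumber = i + 1
        ds.ImagePositionPatient = [0.0, 0.0, float(i) * slice_spacing_mm]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.SliceLocation = float(i) * slice_spacing_mm
        ds.PixelSpacing = [1.0, 1.0]
        if record.kv is not None:
            ds.KVP = record.kv
        if record.rotation_time_s is not None:
            ds.RevolutionTime = record.rotation_time_s
        if record.pitch is not None:
            ds.SpiralPitchFactor = record.pitch
        ds.XRayTubeCurrentInmA = float(ma)
        ds.XRayTubeCurrent = int(round(ma))
        _set_pixels(ds, pixels)
        path = out_dir / f"img{name_order[i]:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


_VIEW_TAGS = {
    "AP": ("AP", [1, 0, 0, 0, 0, -1]),
    "PA": ("PA", [1, 0, 0, 0, 0, -1]),
    "lateral": ("RL", [0, 1, 0, 0, 0, -1]),
}


def write_localizer_dicom(image: np.ndarray, pixel_spacing_mm: float,
                          view: str, path: str | Path, *,
                          accession: str = "SYNTH", index: int = 0) -> Path:
    """Write a localizer radiograph DICOM readable by ``read_localizer``."""
    if view not in _VIEW_TAGS:
        raise InvalidInputError(f"view must be one of {sorted(_VIEW_TAGS)}, got {view!r}")
    view_position, orientation = _VIEW_TAGS[view]
    ds = _base_dataset(_deterministic_uid("localizer", accession, view, index))
    ds.StudyInstanceUID = _deterministic_uid("study", accession)
    ds.SeriesInstanceUID = _deterministic_uid("series-localizer", accession, view)
    ds.AccessionNumber = accession
    ds.ImageType = ["ORIGINAL", "PRIMARY", "LOCALIZER"]
    ds.InstanceNumber = index + 1
    ds.ViewPosition = view_position
    ds.ImageOrientationPatient = orientation
    ds.ImagePositionPatient = [0.0, 0.0, 0.0]
    ds.PixelSpacing = [float(pixel_spacing_mm), float(pixel_spacing_mm)]
    _set_pixels(ds, np.asarray(image))
    path = Path(path)
    ds.save_as(path, enforce_file_format=True)
    return path


def write_demo_dataset(out_dir: str | Path, seed: int = 0, *,
                       n_exams: int = 30) -> dict:
    """Emit a complete demo dataset: localizers, an axial series, truth JSON.

    Used by the ``ctmaster fixtures`` subcommand and the test-suite's
    end-to-end checks.  Returns the manifest of what was written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    phantom = make_localizer(25.0, 35.0, pixel_spacing_mm=1.0, couch=True,
                             noise_sd=10.0, seed=seed)
    ap_path = write_localizer_dicom(phantom.frontal, phantom.pixel_spacing_mm,
                                    "AP", out_dir / "localizer_ap.dcm")
    lat_path = write_localizer_dicom(phantom.lateral, phantom.pixel_spacing_mm,
                                     "lateral", out_dir / "localizer_lat.dcm")
    truth = SizeFitModel.from_params(
        {"p10": (1.8, 0.055), "median": (3.0, 0.055), "p90": (5.0, 0.055)})
    records = simulate_exam_population(truth, n=n_exams, seed=seed)
    series_dir = out_dir / "axial_series"
    series_paths = make_dicom_fixture(records[0], series_dir)
    manifest = {
        "localizers": {"frontal": str(ap_path), "lateral": str(lat_path),
                       "truth": phantom.truth()},
        "axial_series": {"dir": str(series_dir), "n_files": len(series_paths),
                         "ma_values": records[0].ma_values},
        "population_truth": truth.to_dict(),
        "n_exams": n_exams,
        "seed": seed,
    }
    (out_dir / "truth.json").write_text(json.dumps(manifest, indent=2))
    return manifest
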