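"""Patient size from localizer radiographs by smoothed relative thresholding.

A CT localizer (scout) is a planar projection acquired before the scan.  The
patient's width in it is recovered row by row: smooth each detector row with a
Savitzky-Golay filter, saturate the intensity extremes, keep pixels above 30%
of the saturated maximum (which drops the low-intensity couch), and multiply
the surviving pixel count by the pixel spacing.  Averaging over the central
80% of the z range gives a stable width; the AP and lateral widths from the
two standard views sum to the AP+LAT size metric used everywhere else in the
package.

The threshold is relative to the image maximum, so the measurement is
invariant to a global intensity rescale, and it is a pixel-count (not a
max-extent span), so interior holes below threshold reduce the width.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.signal import savgol_filter

from .core import InvalidInputError
from .dicom_io import LocalizerImage

__all__ = ["NoPatientFoundError", "measure_width", "measure_localizer", "patient_size"]


class NoPatientFoundError(InvalidInputError):
    """The image contains no supra-threshold structure to measure."""


def measure_width(image: np.ndarray, pixel_spacing_mm: float, *,
                  z_fraction: float = 0.8,
                  sg_window: int = 15,
                  sg_order: int = 2,
                  saturation_pct: float = 5.0,
                  threshold_frac: float = 0.30,
                  per_row_saturation: bool = False) -> float:
    """Average patient width (cm) across the central rows of a localizer.

    Parameters
    ----------
    image : ndarray, shape (n_z, n_x)
        Localizer pixel data; rows along the patient z axis, columns across
        the patient.
    pixel_spacing_mm : float
        Column spacing in mm/px.
    z_fraction : float
        Central fraction of rows averaged (default 0.8, i.e. the central 80%
        of the z-axis scan range).
    sg_window, sg_order : int
        Savitzky-Golay window (odd, px) and polynomial order applied along
        each row before thresholding.
    saturation_pct : float
        Percentile clip applied to the smoothed image: the highest and lowest
        ``saturation_pct`` percent of values are saturated.
    threshold_frac : float
        Pixels below this fraction of the saturated maximum are excluded;
        0.30 removes a couch at typical couch/body intensity ratios.
    per_row_saturation : bool
        Saturate percentiles per detector row instead of per image.

    Returns
    -------
    float
        Mean supra-threshold row width in cm.

    Raises
    ------
    NoPatientFoundError
        If the saturated image has no positive maximum (e.g. an air image).
    InvalidInputError
        For malformed arguments or an image narrower than the smoothing
        window.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise InvalidInputError(f"image must be 2-D, got shape {image.shape}")
    if not (pixel_spacing_mm > 0 and math.isfinite(pixel_spacing_mm)):
        raise InvalidInputError(f"pixel spacing must be positive, got {pixel_spacing_mm}")
    if not 0 < z_fraction <= 1:
        raise InvalidInputError(f"z_fraction must be in (0, 1], got {z_fraction}")
    if sg_window % 2 == 0 or sg_window <= sg_order:
        raise InvalidInputError(
            f"sg_window must be odd and exceed sg_order, got {sg_window}/{sg_order}")
    if image.shape[1] < sg_window:
        raise InvalidInputError(
            f"image has {image.shape[1]} columns, smaller than the smoothing "
            f"window ({sg_window})")

    smoothed = savgol_filter(image, sg_window, sg_order, axis=1)
    if per_row_saturation:
        lo = np.percentile(smoothed, saturation_pct, axis=1, keepdims=True)
        hi = np.percentile(smoothed, 100 - saturation_pct, axis=1, keepdims=True)
    else:
        lo, hi = np.percentile(smoothed, [saturation_pct, 100 - saturation_pct])
    saturated = np.clip(smoothed, lo, hi)
    peak = float(np.max(saturated))
    if peak <= 0:
        raise NoPatientFoundError("no supra-threshold structure in the image")
    mask = saturated >= threshold_frac * peak

    n_rows = image.shape[0]
    margin = int(round(n_rows * (1 - z_fraction) / 2))
    central = mask[margin:n_rows - margin] if n_rows - 2 * margin > 0 else mask
    widths_px = central.sum(axis=1)
    return float(widths_px.mean() * pixel_spacing_mm / 10.0)


def measure_localizer(localizer: LocalizerImage, **kwargs) -> tuple[str, float]:
    """Measure a localizer, returning which body width it shows and its value.

    A frontal (AP/PA) view projects the patient's lateral width; a lateral
    view projects the anterior-posterior width.  Returns ``(dimension,
    width_cm)`` with dimension ``"lat"``, ``"ap"`` or ``"unknown"``.
    """
    width = measure_width(localizer.pixels, localizer.col_spacing_mm, **kwargs)
    if localizer.is_frontal:
        return "lat", width
    if localizer.view == "lateral":
        return "ap", width
    return "unknown", width


def patient_size(ap_width_cm: float, lat_width_cm: float) -> float:
    """AP+LAT size metric (cm): the sum of the two average widths."""
    for name, v in (("ap_width_cm", ap_width_cm), ("lat_width_cm", lat_width_cm)):
        if not (math.isfinite(v) and v > 0):
            raise InvalidInputError(f"{name} must be positive, got {v}")
    return float(ap_width_cm + lat_width_cm)
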