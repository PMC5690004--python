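"""Per-exam mA distribution summaries, exponential size fits, and mA limits.

An AEC-driven exam produces one tube current per image; the spread over a
thorax-to-pelvis range is large, so exams are summarized by their 10th/50th/
90th mA percentiles rather than quartiles (quartile whiskers flag far too
many points as outliers on such anatomy).  Across a population, each
percentile statistic grows approximately exponentially with patient size s
(AP+LAT, cm):

    mA_stat(s) = a * exp(b * s)

fitted per statistic by least squares in log space.  The 90th-percentile
curve evaluated at a size class's upper end gives the protocol's mA ceiling;
the 10th-percentile curve at the lower end gives the floor.  Rail events —
images whose mA sits at the protocol's configured ceiling or floor — are the
protocol-health surrogate: a railing AEC could not deliver the requested
image quality.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .core import InvalidInputError, ProtocolSpec, SizeClassRule, round_to_station
from .dicom_io import ExamRecord

__all__ = [
    "ExamStats",
    "PercentileFit",
    "SizeFitModel",
    "InsufficientDataError",
    "ExtrapolationWarning",
    "exam_ma_distribution",
    "fit_percentile_curves",
    "derive_ma_limits",
    "detect_rail_events",
]

FIT_STATISTICS = ("p10", "median", "p90")


class InsufficientDataError(InvalidInputError):
    """Too few distinct patient sizes to fit the exponential curves."""


class ExtrapolationWarning(UserWarning):
    """A fitted curve is being evaluated far outside its fitted size support."""


@dataclass
class ExamStats:
    """Box-whisker summary of one exam's per-image mA distribution.

    Percentiles use linear interpolation between order statistics.  Outliers
    are points lying more than ``1.5 * (p90 - p10)`` outside the
    ``[p10, p90]`` band; whiskers span all non-outlier points (and are
    widened to include the percentile band itself in degenerate cases).
    """

    median_ma: float
    p10_ma: float
    p90_ma: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not self.p10_ma <= self.median_ma <= self.p90_ma:
            raise InvalidInputError("percentiles out of order")
        if self.whisker_low > self.p10_ma or self.whisker_high < self.p90_ma:
            raise InvalidInputError("whiskers must span the percentile band")

    def statistic(self, name: str) -> float:
        return {"p10": self.p10_ma, "median": self.median_ma, "p90": self.p90_ma}[name]


def exam_ma_distribution(ma_values, outlier_band_factor: float = 1.5) -> ExamStats:
    """Summarize an exam's mA values into an :class:`ExamStats`.

    Parameters
    ----------
    ma_values : sequence of float
        Per-image average tube currents (non-empty).
    outlier_band_factor : float
        A point is an outlier if it lies more than this multiple of
        ``p90 - p10`` outside the ``[p10, p90]`` band.
    """
    x = np.asarray(list(ma_values), dtype=np.float64)
    if x.size == 0:
        raise InvalidInputError("cannot summarize an empty mA list")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("mA values must be finite")
    p10, median, p90 = np.percentile(x, [10, 50, 90], method="linear")
    band = outlier_band_factor * (p90 - p10)
    is_outlier = (x < p10 - band) | (x > p90 + band)
    inliers = x[~is_outlier]
    # Degenerate distributions can empty one side of the inlier set; the
    # whiskers always cover the percentile band.
    whisker_low = min(float(inliers.min()), float(p10)) if inliers.size else float(p10)
    whisker_high = max(float(inliers.max()), float(p90)) if inliers.size else float(p90)
    return ExamStats(median_ma=float(median), p10_ma=float(p10), p90_ma=float(p90),
                     whisker_low=whisker_low, whisker_high=whisker_high,
                     outliers=tuple(float(v) for v in x[is_outlier]))


@dataclass
class PercentileFit:
    """Fitted ``a * exp(b * s)`` parameters for one percentile statistic."""

    a: float  # mA scale
    b: float  # 1/cm growth rate
    resid_norm: float = 0.0  # log-space residual 2-norm
    n: int = 0

    def __post_init__(self) -> None:
        if not (self.a > 0 and math.isfinite(self.a) and math.isfinite(self.b)):
            raise InvalidInputError(f"invalid fit parameters a={self.a}, b={self.b}")

    def __call__(self, s: float) -> float:
        return self.a * math.exp(self.b * s)


@dataclass
class SizeFitModel:
    """Exponential mA-vs-size fits for the 10th/median/90th percentile curves."""

    fits: dict[str, PercentileFit]
    s_min: float
    s_max: float

    def evaluate(self, statistic: str, s: float) -> float:
        """mA predicted by one statistic's curve at size ``s`` (cm)."""
        if statistic not in self.fits:
            raise InvalidInputError(f"no fit for statistic {statistic!r}")
        return self.fits[statistic](s)

    @classmethod
    def from_params(cls, params: dict[str, tuple[float, float]],
                    s_range: tuple[float, float] = (40.0, 100.0)) -> "SizeFitModel":
        """Build a model from known ``{statistic: (a, b)}`` truth parameters."""
        fits = {k: PercentileFit(a=float(a), b=float(b)) for k, (a, b) in params.items()}
        return cls(fits=fits, s_min=float(s_range[0]), s_max=float(s_range[1]))

    def to_dict(self) -> dict:
        return {"fits": {k: asdict(f) for k, f in self.fits.items()},
                "s_min": self.s_min, "s_max": self.s_max}

    @classmethod
    def from_dict(cls, d: dict) -> "SizeFitModel":
        return cls(fits={k: PercentileFit(**f) for k, f in d["fits"].items()},
                   s_min=float(d["s_min"]), s_max=float(d["s_max"]))

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "SizeFitModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_percentile_curves(points, statistics=FIT_STATISTICS) -> SizeFitModel:
    """Fit ``a * exp(b * s)`` to each percentile statistic across exams.

    The fit is ordinary least squares on ``ln(stat) = ln(a) + b * s`` —
    exactly the stated model class, convex, and exact on noiseless
    exponential data.

    Parameters
    ----------
    points : sequence of (float, ExamStats)
        Patient size (cm) and mA summary per exam; at least 3 distinct sizes.
    statistics : sequence of str
        Which statistics to fit (default all three).
    """
    points = list(points)
    sizes = np.asarray([s for s, _stats in points], dtype=np.float64)
    if np.unique(sizes).size < 3:
        raise InsufficientDataError(
            f"need >= 3 distinct sizes to fit, got {np.unique(sizes).size}")
    fits: dict[str, PercentileFit] = {}
    for stat in statistics:
        y = np.asarray([st.statistic(stat) for _s, st in points], dtype=np.float64)
        if np.any(y <= 0):
            raise InvalidInputError(f"{stat} values must be positive for a log-space fit")
        coeffs, residuals, *_ = np.polyfit(sizes, np.log(y), 1, full=True)
        resid_norm = float(np.sqrt(residuals[0])) if residuals.size else 0.0
        fits[stat] = PercentileFit(a=float(np.exp(coeffs[1])), b=float(coeffs[0]),
                                   resid_norm=resid_norm, n=len(points))
    return SizeFitModel(fits=fits, s_min=float(sizes.min()), s_max=float(sizes.max()))


def derive_ma_limits(fit: SizeFitModel, size_class: str,
                     rule: SizeClassRule | None = None,
                     ma_station_step: float = 5.0,
                     ma_floor: float | None = None,
                     size_margin_cm: float = 0.0,
                     extrapolation_limit_cm: float = 25.0) -> tuple[float, float]:
    """Protocol (ma_min, ma_max) for a size class from the fitted curves.

    ``ma_max`` is the 90th-percentile curve at the class's upper evaluation
    size (100 cm for the unbounded large class); ``ma_min`` is the
    10th-percentile curve at the class's lower bound.  Both snap to the
    nearest mA station, and ``ma_min`` is then clamped up to any configured
    scanner/radiologist floor.  ``size_margin_cm`` optionally evaluates at a
    slightly smaller/larger size than the class bounds, since scanner-reported
    mA values are rotation averages.

    Emits :class:`ExtrapolationWarning` when an evaluation size lies more
    than ``extrapolation_limit_cm`` outside the fitted size support.
    """
    rule = rule or SizeClassRule.default()
    if size_class not in rule.class_bounds:
        raise InvalidInputError(f"unknown size class {size_class!r}")
    s_hi = rule.eval_size_for_max(size_class) + size_margin_cm
    s_lo = max(rule.lower(size_class) - size_margin_cm, 0.0)
    for s_eval, what in ((s_hi, "ma_max"), (s_lo, "ma_min")):
        if s_eval < fit.s_min - extrapolation_limit_cm or s_eval > fit.s_max + extrapolation_limit_cm:
            warnings.warn(
                f"{what} evaluated at {s_eval:.1f} cm, more than "
                f"{extrapolation_limit_cm:.0f} cm outside the fitted size range "
                f"[{fit.s_min:.1f}, {fit.s_max:.1f}] cm", ExtrapolationWarning)
    ma_max = round_to_station(fit.evaluate("p90", s_hi), ma_station_step)
    ma_min = round_to_station(fit.evaluate("p10", s_lo), ma_station_step)
    if ma_floor is not None:
        ma_min = max(ma_min, float(ma_floor))
    return ma_min, ma_max


def detect_rail_events(record: ExamRecord, protocol: ProtocolSpec,
                       tolerance_ma: float = 1.0) -> tuple[float, float]:
    """Fractions of an exam's images at the protocol's mA ceiling and floor.

    An image is a ceiling event when its mA is within ``tolerance_ma`` of
    ``protocol.ma_max`` (and a floor event symmetrically).  Non-zero ceiling
    fractions for the largest patients mean the AEC could not deliver the
    requested image quality; floor fractions flag unnecessary dose unless the
    floor was raised deliberately.
    """
    if not record.ma_values:
        raise InvalidInputError("exam record has no mA values")
    ma = np.asarray(record.ma_values, dtype=np.float64)
    ceiling_frac = float(np.mean(ma >= protocol.ma_max - tolerance_ma))
    floor_frac = float(np.mean(ma <= protocol.ma_min + tolerance_ma))
    return ceiling_frac, floor_frac
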