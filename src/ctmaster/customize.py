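"""Analytic protocol customization: mA scaling rules, factors, and trade-offs.

Two scaling rules relate the AEC mA demand of a derived ("new master")
protocol to that of the measured original.  Creating a new quality tier on
the *same* scanner (a contrast-to-noise change) uses

    mA_new = mA_orig * (t_orig * P_new) / (t_new * P_orig)
                     * (NI_orig / NI_new)^2 * FkV * FD            (within)

while customizing the same anatomical protocol to a *different* scanner uses

    mA_new = mA_orig * (t_orig * P_new) / (t_new * P_orig)
                     * FkV * FD * FG                              (cross)

with NI values normalized to a common reference slice thickness before use.
The multiplicative factors are: FG, inverse-square geometry,
``(SID_new/SID_orig)^2``; FkV, the equal-CNR beam-energy factor,
``noise_mA_factor / contrast_ratio^2``; FD, the equal-low-contrast-
detectability dose ratio of a denoiser; and a pass-through scanner-specific
FSS (default 1).  Both rules conserve effective mAs (mA*t/P) when quality,
energy and geometry are unchanged.

Scan duration for a scan length d follows from the table speed:

    t_d = (t * d) / (P * N * T)

with N detector rows of z-thickness T at isocenter.  ``enumerate_options``
applies these rules over a candidate parameter grid and flags every option
whose scaled mA ceiling exceeds what the target scanner can deliver,
turning the "which knob do we turn" discussion into a ranked table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import (InvalidInputError, ProtocolSpec, ScannerModel,
                   rescale_noise_index, round_to_station)

__all__ = [
    "FactorSet",
    "FeasibilityReport",
    "CustomizationResult",
    "eq1_scale",
    "eq2_scale",
    "compute_fg",
    "compute_fkv",
    "compute_fd",
    "dose_change_ratio",
    "scan_duration",
    "customize_protocol",
    "enumerate_options",
]


def _positive(**named: float) -> None:
    for name, v in named.items():
        if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
            raise InvalidInputError(f"{name} must be positive and finite, got {v!r}")


@dataclass(frozen=True)
class FactorSet:
    """Multiplicative mA-scaling factors applied during customization.

    All default to 1 (no change).  ``fg`` applies only to cross-scanner moves;
    ``fss`` is a pass-through residual for scanner pairs whose filtration or
    detector response differ (no formula is modeled for it).
    """

    fg: float = 1.0
    fkv: float = 1.0
    fd: float = 1.0
    fss: float = 1.0

    def __post_init__(self) -> None:
        _positive(fg=self.fg, fkv=self.fkv, fd=self.fd, fss=self.fss)


def eq1_scale(t_orig: float, p_orig: float, ni_orig: float,
              t_new: float, p_new: float, ni_new: float,
              f: FactorSet | None = None) -> float:
    """Within-scanner mA scale factor for a quality (CNR) change.

    NI values must be normalized to the same reference slice thickness
    (:func:`ctmaster.core.rescale_noise_index`) before calling.
    """
    f = f or FactorSet()
    _positive(t_orig=t_orig, p_orig=p_orig, ni_orig=ni_orig,
              t_new=t_new, p_new=p_new, ni_new=ni_new)
    return ((t_orig * p_new) / (t_new * p_orig)
            * (ni_orig / ni_new) ** 2 * f.fkv * f.fd * f.fss)


def eq2_scale(t_orig: float, p_orig: float, t_new: float, p_new: float,
              f: FactorSet | None = None) -> float:
    """Cross-scanner mA scale factor for the same anatomical protocol.

    Quality is held fixed (equal CNR / LCD), so no NI term appears; beam
    energy, denoiser and geometry changes enter through the factor set.
    """
    f = f or FactorSet()
    _positive(t_orig=t_orig, p_orig=p_orig, t_new=t_new, p_new=p_new)
    return (t_orig * p_new) / (t_new * p_orig) * f.fkv * f.fd * f.fg * f.fss


def compute_fg(sid_orig_mm: float, sid_new_mm: float) -> float:
    """Geometry factor: squared SID ratio from inverse-square detector dose."""
    _positive(sid_orig_mm=sid_orig_mm, sid_new_mm=sid_new_mm)
    return (sid_new_mm / sid_orig_mm) ** 2


def compute_fkv(contrast_ratio: float, noise_ma_factor: float) -> float:
    """Equal-CNR beam-energy factor from its two measured parts.

    ``contrast_ratio`` is HU(low kV)/HU(high kV) for the material of interest;
    ``noise_ma_factor`` is the squared image-noise ratio at equal effective
    mAs (the mA change holding noise constant).  Holding CNR fixed while the
    contrast rises by ``contrast_ratio`` lets the noise rise by the same
    ratio, so the mA changes by ``noise_ma_factor / contrast_ratio**2``.
    """
    _positive(contrast_ratio=contrast_ratio, noise_ma_factor=noise_ma_factor)
    return noise_ma_factor / contrast_ratio ** 2


def compute_fd(ctdi_with_denoiser: float, ctdi_without: float) -> float:
    """Denoiser factor: the equal-LCD dose ratio with/without the denoiser."""
    _positive(ctdi_with_denoiser=ctdi_with_denoiser, ctdi_without=ctdi_without)
    return ctdi_with_denoiser / ctdi_without


def dose_change_ratio(fkv: float, kv_ctdi_adjustment: float) -> float:
    """Equal-CNR dose ratio accompanying a kV change.

    ``kv_ctdi_adjustment`` is the manufacturer's CTDIvol-per-mAs factor
    between the two stations; the patient dose changes by
    ``fkv / kv_ctdi_adjustment`` when the mA is rescaled for equal CNR.
    """
    _positive(fkv=fkv, kv_ctdi_adjustment=kv_ctdi_adjustment)
    return fkv / kv_ctdi_adjustment


def scan_duration(t: float, p: float, d_cm: float, n_rows: int, t_elem_mm: float) -> float:
    """Scan duration (s) of a helical acquisition of length ``d_cm``."""
    _positive(t=t, p=p, d_cm=d_cm, n_rows=n_rows, t_elem_mm=t_elem_mm)
    return (t * d_cm * 10.0) / (p * n_rows * t_elem_mm)


@dataclass
class FeasibilityReport:
    """Whether a customized protocol fits the target scanner's mA envelope."""

    feasible: bool
    ma_ceiling: float | None = None
    ceiling_margin_pct: float | None = None  # % of ceiling left above ma_max
    floor_margin_pct: float | None = None    # % of ma_min above the scanner floor
    duration_s: float | None = None
    messages: list[str] = field(default_factory=list)


@dataclass
class CustomizationResult:
    """A derived protocol with its scale factor, feasibility and provenance."""

    new_protocol: ProtocolSpec
    scale_factor: float
    feasibility: FeasibilityReport
    provenance: dict = field(default_factory=dict)


def _feasibility(protocol: ProtocolSpec, scanner: ScannerModel | None) -> FeasibilityReport:
    messages: list[str] = []
    if scanner is None:
        return FeasibilityReport(feasible=True,
                                 messages=["no scanner attached; envelope not checked"])
    if int(protocol.kv) not in scanner.kv_stations:
        return FeasibilityReport(
            feasible=False,
            messages=[f"{protocol.kv} kV is not a station of {scanner.model_name}"])
    ceiling = scanner.ma_ceiling_by_kv.get(int(protocol.kv))
    feasible = True
    ceiling_margin = None
    if ceiling is None:
        messages.append(f"no mA ceiling known at {protocol.kv} kV; not checked")
    else:
        ceiling_margin = 100.0 * (ceiling - protocol.ma_max) / ceiling
        if protocol.ma_max > ceiling:
            feasible = False
            messages.append(
                f"ma_max {protocol.ma_max:.0f} exceeds the {ceiling:.0f} mA "
                f"ceiling at {protocol.kv} kV")
    floor_margin = None
    if scanner.ma_floor > 0:
        floor_margin = 100.0 * (protocol.ma_min - scanner.ma_floor) / scanner.ma_floor
    duration = None
    if protocol.scan_length_cm:
        duration = scan_duration(protocol.t, protocol.p, protocol.scan_length_cm,
                                 scanner.n_rows, scanner.t_elem_mm)
    return FeasibilityReport(feasible=feasible, ma_ceiling=ceiling,
                             ceiling_margin_pct=ceiling_margin,
                             floor_margin_pct=floor_margin,
                             duration_s=duration, messages=messages)


def customize_protocol(orig: ProtocolSpec, target: dict | None = None,
                       f: FactorSet | None = None, mode: str = "within",
                       ma_station_step: float = 5.0,
                       ma_floor: float | None = None) -> CustomizationResult:
    """Derive a new protocol from a measured original.

    Parameters
    ----------
    orig : ProtocolSpec
        The master protocol whose mA range was derived from measured mA
        demand data.
    target : dict, optional
        Changed parameters: any of ``name``, ``master_id``, ``kv``, ``t``,
        ``p``, ``ni``, ``ref_thickness_mm``, ``scan_length_cm``,
        ``size_class`` and ``scanner`` (a :class:`ScannerModel`).  Omitted
        parameters carry over from the original.
    f : FactorSet, optional
        Customization factors; defaults to all ones.
    mode : {"within", "cross"}
        ``"within"`` applies the NI-aware quality-change rule on one scanner;
        ``"cross"`` applies the equal-quality cross-scanner rule.
    ma_station_step : float
        mA station spacing for snapping the scaled limits.
    ma_floor : float, optional
        Radiologist/scanner minimum-mA policy; the scaled ``ma_min`` is
        clamped up to it after station rounding.  Defaults to the target
        scanner's floor.

    Notes
    -----
    A scaled ``ma_max`` above the target scanner's ceiling is recorded as a
    feasibility failure in the result, not raised as an exception — rejected
    options are part of the trade-off analysis.
    """
    target = dict(target or {})
    f = f or FactorSet()
    scanner = target.pop("scanner", orig.scanner)
    kv = int(target.pop("kv", orig.kv))
    t = float(target.pop("t", orig.t))
    p = float(target.pop("p", orig.p))
    ni = float(target.pop("ni", orig.ni))
    ref_thk = float(target.pop("ref_thickness_mm", orig.ref_thickness_mm))
    name = target.pop("name", f"{orig.name} (customized)")
    master_id = target.pop("master_id", orig.master_id)
    scan_length = target.pop("scan_length_cm", orig.scan_length_cm)
    size_class = target.pop("size_class", orig.size_class)
    if target:
        raise InvalidInputError(f"unknown target fields: {sorted(target)}")

    if mode == "within":
        ni_new_star = rescale_noise_index(ni, ref_thk, orig.ref_thickness_mm)
        scale = eq1_scale(orig.t, orig.p, orig.ni, t, p, ni_new_star, f)
    elif mode == "cross":
        scale = eq2_scale(orig.t, orig.p, t, p, f)
    else:
        raise InvalidInputError(f"mode must be 'within' or 'cross', got {mode!r}")

    raw_min, raw_max = orig.ma_min * scale, orig.ma_max * scale
    ma_max = round_to_station(raw_max, ma_station_step)
    ma_min = round_to_station(raw_min, ma_station_step)
    floor = ma_floor if ma_floor is not None else (scanner.ma_floor if scanner else None)
    if floor is not None:
        ma_min = max(ma_min, float(floor))

    new_protocol = ProtocolSpec(
        name=name, master_id=master_id, kv=kv, ma_min=ma_min, ma_max=ma_max,
        t=t, p=p, ni=ni, ref_thickness_mm=ref_thk, scan_length_cm=scan_length,
        size_class=size_class, scanner=scanner)
    feasibility = _feasibility(new_protocol, scanner)
    provenance = {
        "original": orig.name, "mode": mode, "factors": asdict(f),
        "scale_factor": scale, "ma_min_unrounded": raw_min,
        "ma_max_unrounded": raw_max, "ma_floor_applied": floor,
        "ma_station_step": ma_station_step,
    }
    return CustomizationResult(new_protocol=new_protocol, scale_factor=scale,
                               feasibility=feasibility, provenance=provenance)


def _expand_grid(grid) -> list[dict]:
    if isinstance(grid, dict):
        from itertools import product
        keys = list(grid)
        return [dict(zip(keys, combo)) for combo in product(*(grid[k] for k in keys))]
    return [dict(c) for c in grid]


def enumerate_options(orig: ProtocolSpec, scanner: ScannerModel, grid,
                      factor_resolver=None, *, mode: str = "cross",
                      max_duration_s: float | None = None,
                      d_cm: float | None = None) -> pd.DataFrame:
    """Rank candidate parameter choices for customizing a protocol.

    Parameters
    ----------
    orig : ProtocolSpec
        The measured original protocol.
    scanner : ScannerModel
        The target scanner whose mA envelope constrains the options.
    grid : list of dict, or dict of lists
        Candidates over ``kv``/``t``/``p``/``ni`` (missing keys default to
        the original's values; an optional ``label`` names the row).  A dict
        of lists is expanded as a full factorial grid.
    factor_resolver : callable, optional
        ``factor_resolver(orig, candidate) -> FactorSet``; defaults to unit
        factors for every candidate.
    mode : {"cross", "within"}
        Scaling rule.  Cross-scanner customization holds image quality fixed,
        so a candidate's ``ni`` is carried as metadata (the CNR-compensating
        NI that accompanies a kV change) and does not enter the mA scaling.
    max_duration_s : float, optional
        Clinical scan-time constraint; slower candidates are flagged
        infeasible.
    d_cm : float, optional
        Scan length for the duration column; defaults to the original's.

    Returns
    -------
    pandas.DataFrame
        One row per candidate with the scaled maximum mA, scan duration and
        feasibility flag.  Infeasible rows are retained (flagged, with the
        reason) so rejected options remain visible; feasible rows sort first,
        by duration.
    """
    candidates = _expand_grid(grid)
    if not candidates:
        raise InvalidInputError("candidate grid is empty")
    d = d_cm if d_cm is not None else orig.scan_length_cm
    rows = []
    for i, cand in enumerate(candidates):
        kv = int(cand.get("kv", orig.kv))
        t = float(cand.get("t", orig.t))
        p = float(cand.get("p", orig.p))
        ni = float(cand.get("ni", orig.ni))
        f = factor_resolver(orig, cand) if factor_resolver else FactorSet()
        if mode == "cross":
            scale = eq2_scale(orig.t, orig.p, t, p, f)
        elif mode == "within":
            scale = eq1_scale(orig.t, orig.p, orig.ni, t, p, ni, f)
        else:
            raise InvalidInputError(f"mode must be 'within' or 'cross', got {mode!r}")
        ma_max = orig.ma_max * scale
        td = scan_duration(t, p, d, scanner.n_rows, scanner.t_elem_mm) if d else np.nan
        reasons = []
        ceiling = scanner.ma_ceiling_by_kv.get(kv)
        if kv not in scanner.kv_stations:
            reasons.append(f"{kv} kV not available")
        elif ceiling is not None and ma_max > ceiling + 1e-9:
            reasons.append(f"needs {ma_max:.0f} mA, scanner limit {ceiling:.0f} mA at {kv} kV")
        if max_duration_s is not None and np.isfinite(td) and td > max_duration_s:
            reasons.append(f"duration {td:.1f} s exceeds limit {max_duration_s:.1f} s")
        rows.append({"label": cand.get("label", f"option {i + 1}"),
                     "kv": kv, "t": t, "p": p, "ni": ni,
                     "ma_max": ma_max, "td_s": td,
                     "feasible": not reasons, "reason": "; ".join(reasons)})
    table = pd.DataFrame(rows)
    table = table.sort_values(["feasible", "td_s"], ascending=[False, True],
                              kind="stable", na_position="last")
    return table.reset_index(drop=True)
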