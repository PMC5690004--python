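"""End-to-end demo pipeline: measure -> stats -> fit -> limits -> customize.

Driven by one YAML config, the pipeline runs every stage of the
protocol-management workflow on synthetic data with known truth: measure
patient size from generated localizers, summarize and fit the simulated mA
demand, derive a size class's mA limits, customize the protocol to a target
scanner, and check feasibility against that scanner's mA envelope.  All
artifacts (CSV/JSON tables, a box-whisker-vs-size plot, a Markdown report)
are deterministic for a fixed config and seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .config import Catalog, example_catalog, load_catalog
from .core import InvalidInputError, SizeClassRule
from .customize import FactorSet, customize_protocol
from .dicom_io import write_exam_table
from .ma_stats import SizeFitModel, derive_ma_limits, exam_ma_distribution, fit_percentile_curves
from .plotting import plot_ma_vs_size
from .size import measure_width
from .synthetic import make_localizer, simulate_exam_population

__all__ = ["ConfigError", "load_config", "run_pipeline"]


class ConfigError(InvalidInputError):
    """Config schema violation with field-level messages."""


_DEFAULT_TRUTH = {"p10": (1.8, 0.055), "median": (3.0, 0.055), "p90": (5.0, 0.055)}


def _check(errors: list[str], cond: bool, message: str) -> bool:
    if not cond:
        errors.append(message)
    return cond


def load_config(path_or_dict) -> dict:
    """Load and validate a pipeline config, raising ConfigError on violations."""
    if isinstance(path_or_dict, (str, Path)):
        cfg = yaml.safe_load(Path(path_or_dict).read_text())
    else:
        cfg = dict(path_or_dict)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    errors: list[str] = []

    cfg.setdefault("seed", 0)
    _check(errors, isinstance(cfg["seed"], int), "seed: must be an integer")
    _check(errors, "output_dir" in cfg, "output_dir: required")

    pop = cfg.setdefault("population", {})
    pop.setdefault("truth", dict(_DEFAULT_TRUTH))
    pop.setdefault("n", 200)
    pop.setdefault("noise_cv", 0.10)
    pop.setdefault("size_distribution", {"mean": 62.0, "sd": 10.0, "range": [40.0, 100.0]})
    _check(errors, isinstance(pop["n"], int) and pop["n"] >= 3,
           "population.n: must be an integer >= 3")
    for stat in ("p10", "median", "p90"):
        entry = pop["truth"].get(stat)
        _check(errors, isinstance(entry, (list, tuple)) and len(entry) == 2,
               f"population.truth.{stat}: must be [a, b]")

    catalog_path = cfg.get("catalog")
    catalog = load_catalog(catalog_path) if catalog_path else example_catalog()
    cfg["_catalog"] = catalog

    proto_name = cfg.get("protocol")
    if _check(errors, isinstance(proto_name, str) and bool(proto_name),
              "protocol: required (a protocol name from the catalog)"):
        _check(errors, proto_name in catalog.protocols,
               f"protocol: unknown protocol {proto_name!r}; "
               f"catalog has {sorted(catalog.protocols)}")

    cfg.setdefault("size_class", "medium")
    _check(errors, cfg["size_class"] in ("small", "medium", "large"),
           f"size_class: must be small|medium|large, got {cfg['size_class']!r}")

    limits = cfg.setdefault("limits", {})
    limits.setdefault("ma_station_step", 5.0)
    limits.setdefault("ma_floor", None)

    cust = cfg.setdefault("customize", None)
    if cust is not None:
        target_name = cust.get("target_scanner")
        if _check(errors, isinstance(target_name, str) and bool(target_name),
                  "customize.target_scanner: required"):
            _check(errors, target_name in catalog.scanners,
                   f"customize.target_scanner: unknown scanner {target_name!r}; "
                   f"catalog has {sorted(catalog.scanners)}")
        cust.setdefault("mode", "cross")
        _check(errors, cust["mode"] in ("within", "cross"),
               f"customize.mode: must be within|cross, got {cust['mode']!r}")
        cust.setdefault("target", {})
        cust.setdefault("factors", {})

    measure = cfg.setdefault("measure", {})
    measure.setdefault("n_localizers", 3)
    cfg.setdefault("strict", False)

    if errors:
        raise ConfigError("invalid config:\n  " + "\n  ".join(errors))
    return cfg


def run_pipeline(config) -> dict:
    """Run the full pipeline from a config path/dict; returns the report bundle.

    The bundle maps artifact names to paths plus the headline numbers
    (fitted parameters, derived limits, customization feasibility).
    """
    cfg = load_config(config)
    catalog: Catalog = cfg["_catalog"]
    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg["seed"]
    protocol = catalog.protocol(cfg["protocol"])
    rule = catalog.size_rule

    # --- measure: localizer phantoms through the width pipeline ------------
    pop = cfg["population"]
    sd = pop["size_distribution"]
    size_rows = []
    for i in range(cfg["measure"]["n_localizers"]):
        ap = 20.0 + 4.0 * i
        lat = 26.0 + 4.0 * i
        phantom = make_localizer(ap, lat, pixel_spacing_mm=1.0, couch=True,
                                 noise_sd=10.0, seed=seed + i)
        meas_lat = measure_width(phantom.frontal, phantom.pixel_spacing_mm)
        meas_ap = measure_width(phantom.lateral, phantom.pixel_spacing_mm)
        size_rows.append({"phantom": i, "true_ap_cm": ap, "true_lat_cm": lat,
                          "meas_ap_cm": round(meas_ap, 3),
                          "meas_lat_cm": round(meas_lat, 3),
                          "meas_sum_cm": round(meas_ap + meas_lat, 3)})
    sizes_csv = out / "sizes.csv"
    pd.DataFrame(size_rows).to_csv(sizes_csv, index=False)

    # --- simulate population and summarize ---------------------------------
    truth = SizeFitModel.from_params(
        {k: tuple(v) for k, v in pop["truth"].items()},
        s_range=tuple(sd["range"]))
    records = simulate_exam_population(
        truth, size_distribution=(sd["mean"], sd["sd"], tuple(sd["range"])),
        n=pop["n"], noise_cv=pop["noise_cv"], protocol=None, seed=seed)
    exams_csv = write_exam_table(records, out / "exams.csv")

    points = [(rec.size_sum_cm, exam_ma_distribution(rec.ma_values)) for rec in records]
    stats_rows = [{"size_sum_cm": s, "p10_ma": st.p10_ma, "median_ma": st.median_ma,
                   "p90_ma": st.p90_ma, "whisker_low": st.whisker_low,
                   "whisker_high": st.whisker_high, "n_outliers": len(st.outliers)}
                  for s, st in points]
    stats_csv = out / "stats.csv"
    pd.DataFrame(stats_rows).to_csv(stats_csv, index=False)

    # --- fit and limits -----------------------------------------------------
    fit = fit_percentile_curves(points)
    fit_json = fit.save(out / "fit.json")
    ma_min, ma_max = derive_ma_limits(
        fit, cfg["size_class"], rule=rule,
        ma_station_step=cfg["limits"]["ma_station_step"],
        ma_floor=cfg["limits"]["ma_floor"])
    limits_json = out / "limits.json"
    limits_json.write_text(json.dumps(
        {"size_class": cfg["size_class"], "ma_min": ma_min, "ma_max": ma_max}, indent=2))

    plot_png = plot_ma_vs_size(points, fit=fit, limits=(ma_min, ma_max),
                               path=out / "ma_vs_size.png",
                               title=f"{protocol.name}: mA demand vs size")

    # --- customize ----------------------------------------------------------
    customization = None
    cust_json = None
    if cfg["customize"]:
        cust = cfg["customize"]
        target = dict(cust["target"])
        target["scanner"] = catalog.scanner(cust["target_scanner"])
        result = customize_protocol(protocol, target=target,
                                    f=FactorSet(**cust["factors"]),
                                    mode=cust["mode"])
        customization = {
            "new_protocol": {"name": result.new_protocol.name,
                             "kv": result.new_protocol.kv,
                             "ma_min": result.new_protocol.ma_min,
                             "ma_max": result.new_protocol.ma_max,
                             "t": result.new_protocol.t,
                             "p": result.new_protocol.p,
                             "ni": result.new_protocol.ni},
            "scale_factor": result.scale_factor,
            "feasible": result.feasibility.feasible,
            "ceiling_margin_pct": result.feasibility.ceiling_margin_pct,
            "duration_s": result.feasibility.duration_s,
            "messages": result.feasibility.messages,
        }
        cust_json = out / "customization.json"
        cust_json.write_text(json.dumps(customization, indent=2))

    # --- report -------------------------------------------------------------
    fit_summary = {k: {"a": f.a, "b": f.b} for k, f in fit.fits.items()}
    report = [
        f"# ctmaster pipeline report (ctmaster {__version__})",
        "",
        f"- protocol: {protocol.name} ({protocol.master_id})",
        f"- exams simulated: {pop['n']} (seed {seed})",
        f"- fitted curves: " + ", ".join(
            f"{k}: a={v['a']:.4g}, b={v['b']:.4g}" for k, v in fit_summary.items()),
        f"- derived {cfg['size_class']}-class limits: {ma_min:g}-{ma_max:g} mA",
    ]
    if customization:
        report.append(
            f"- customized to {cfg['customize']['target_scanner']}: "
            f"{customization['new_protocol']['ma_min']:g}-"
            f"{customization['new_protocol']['ma_max']:g} mA, "
            f"feasible={customization['feasible']}")
    report_md = out / "report.md"
    report_md.write_text("\n".join(report) + "\n")

    bundle = {
        "artifacts": {"sizes_csv": str(sizes_csv), "exams_csv": str(exams_csv),
                      "stats_csv": str(stats_csv), "fit_json": str(fit_json),
                      "limits_json": str(limits_json), "plot_png": str(plot_png),
                      "report_md": str(report_md),
                      "customization_json": str(cust_json) if cust_json else None},
        "fit": fit_summary,
        "limits": {"ma_min": ma_min, "ma_max": ma_max},
        "customization": customization,
    }
    if cfg["strict"] and customization and not customization["feasible"]:
        raise InvalidInputError("strict mode: customization infeasible on target scanner")
    return bundle
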