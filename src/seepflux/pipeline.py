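"""Stage orchestration: run configured stages in order with a run report.

Each run writes a machine-readable JSON report recording the config hash,
seed, package version, input checksums and every output produced, so a
rerun with the same config and seed is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

from . import __version__
from .config import PipelineConfig
from .constants import PhysicalConstants
from .coupons import coupon_areal_dissolution, fit_dissolution_rate
from .io import (
    load_table1_sites,
    read_calibration_csv,
    read_coupon_csv,
    read_rois_geojson,
    read_scalebars,
    read_sites_csv,
    read_stack_npz,
    write_dissolution_csv,
    write_profile_csv,
)
from .phimaging import (
    KymographSpec,
    compute_ratio_image,
    extract_kymograph,
    fit_calibration,
)
from .seafloor import coverage_fractions, fit_perspective_scale
from .upscaling import (
    PrecipitationFlux,
    convert_rate_units,
    propagate_rate_se,
    site_flux,
    summarize_global,
)

log = logging.getLogger("seepflux")

#: Stage execution order; downstream stages are skipped if a dependency failed.
STAGE_ORDER = ("rates", "phmap", "coverage", "upscale")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.model_dump(mode="json"), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(config: PipelineConfig, report_path=None) -> dict:
    """Execute the configured stages and return the run report dict."""
    report: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
        "ok": True,
    }
    constants = PhysicalConstants(
        aragonite_density=config.constants.aragonite_density,
        caco3_molar_mass=config.constants.caco3_molar_mass,
        carbon_molar_mass=config.constants.carbon_molar_mass,
        hours_per_year=config.constants.hours_per_year,
    )
    for name in STAGE_ORDER:
        stage_cfg = getattr(config.stages, name)
        if stage_cfg is None:
            continue
        entry: dict = {"status": "ok", "inputs": {}, "outputs": {}}
        try:
            runner = globals()[f"_run_{name}"]
            runner(config, constants, stage_cfg, entry)
        except Exception as exc:  # recorded, not raised: report carries status
            entry["status"] = "error"
            entry["error"] = f"{type(exc).__name__}: {exc}"
            report["ok"] = False
            log.error("stage %s failed: %s", name, entry["error"])
        report["stages"][name] = entry
    if report_path is not None:
        Path(report_path).parent.mkdir(parents=True, exist_ok=True)
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=1)
    return report


def _record_input(entry: dict, path) -> None:
    entry["inputs"][str(path)] = _sha256(Path(path))


def _stamp(config: PipelineConfig, payload: dict) -> dict:
    payload["config_hash"] = _config_hash(config)
    payload["seed"] = config.seed
    return payload


def _run_rates(config, constants, cfg, entry) -> None:
    records = read_coupon_csv(cfg.coupons)
    _record_input(entry, cfg.coupons)
    diss = [
        coupon_areal_dissolution(r, constants, config.options.mass_for_area)
        for r in records
    ]
    summary = {}
    for cond in sorted({d.condition for d in diss}):
        rate = fit_dissolution_rate(
            diss, cond, force_origin=config.options.force_origin, constants=constants
        )
        summary[cond] = {
            "rate": rate.rate,
            "rate_se": rate.rate_se,
            "n": rate.n_coupons,
            "slope": rate.slope_per_hour,
            "intercept": rate.intercept,
        }
        log.info(
            "%s: %.2f (±%.2f) umol CaCO3 cm^-2 yr^-1 (n=%d)",
            cond, rate.rate, rate.rate_se, rate.n_coupons,
        )
    out = Path(cfg.out)
    out.parent.mkdir(parents=True, exist_ok=True)
    csv_out = out.with_suffix(".csv")
    write_dissolution_csv(diss, csv_out)
    with open(out, "w") as fh:
        json.dump(_stamp(config, {"conditions": summary}), fh, indent=1)
    entry["outputs"]["summary"] = str(out)
    entry["outputs"]["dissolutions"] = str(csv_out)


def _run_phmap(config, constants, cfg, entry) -> None:
    stack = read_stack_npz(cfg.stack_npz)
    _record_input(entry, cfg.stack_npz)
    points = read_calibration_csv(cfg.calibration)
    _record_input(entry, cfg.calibration)
    curve = fit_calibration(points, form=config.options.calibration_form)
    ratio = compute_ratio_image(stack)
    spec = KymographSpec(
        start_um=tuple(cfg.kymograph["start_um"]),
        end_um=tuple(cfg.kymograph["end_um"]),
        width_um=float(cfg.kymograph.get("width_um", 13.0)),
        depth_range_um=tuple(cfg.kymograph["depth_range_um"])
        if "depth_range_um" in cfg.kymograph
        else None,
    )
    profile = extract_kymograph(
        ratio, spec, curve, averaging=config.options.kymograph_averaging
    )
    prefix = Path(cfg.out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    profile_csv = prefix.with_name(prefix.name + "_profile.csv")
    write_profile_csv(profile, profile_csv)
    summary_json = prefix.with_name(prefix.name + "_summary.json")
    with open(summary_json, "w") as fh:
        json.dump(_stamp(config, dict(profile.summary)), fh, indent=1)
    log.info("pH profile summary: %s", profile.summary)
    entry["outputs"]["profile"] = str(profile_csv)
    entry["outputs"]["summary"] = str(summary_json)


def _run_coverage(config, constants, cfg, entry) -> None:
    rois = read_rois_geojson(cfg.rois)
    _record_input(entry, cfg.rois)
    fg, bg = read_scalebars(cfg.scalebars)
    image_size = tuple(cfg.scalebars.get("image_size", (1333, 750)))
    model = fit_perspective_scale(fg, bg, image_size)
    totals = [r for r in rois if r.role == "total_visible"]
    if len(totals) != 1:
        raise ValueError(f"expected exactly one total_visible ROI, got {len(totals)}")
    result = coverage_fractions(
        model,
        totals[0],
        [r for r in rois if r.role == "rock"],
        [r for r in rois if r.role == "negative"],
    )
    payload = {
        "total_area_m2": result.total_area_m2,
        "rock_area_m2": result.rock_area_m2,
        "mat_area_m2": result.mat_area_m2,
        "mat_rock_fraction_pct": result.mat_rock_fraction_pct,
        "rock_total_fraction_pct": result.rock_total_fraction_pct,
        "mat_total_fraction_pct": result.mat_total_fraction_pct,
    }
    log.info(
        "coverage: total %.2f m^2, rock %.2f m^2 (%.1f%%), mat %.2f m^2 (%.1f%% of rock)",
        result.total_area_m2, result.rock_area_m2, result.rock_total_fraction_pct,
        result.mat_area_m2, result.mat_rock_fraction_pct,
    )
    out = Path(cfg.out)
    out.parent.mkdir(parents=True, exist_ok=True)
    with open(out, "w") as fh:
        json.dump(_stamp(config, payload), fh, indent=1)
    entry["outputs"]["coverage"] = str(out)


def _run_upscale(config, constants, cfg, entry) -> None:
    if cfg.sites is not None:
        sites = read_sites_csv(cfg.sites)
        _record_input(entry, cfg.sites)
    else:
        sites = load_table1_sites()
    c = config.constants
    rate_m2 = convert_rate_units(c.rate_umol_cm2_yr)
    fluxes = []
    per_site = []
    for s in sites:
        f = site_flux(rate_m2, s, c.mat_fraction)
        f = propagate_rate_se(f, c.rate_umol_cm2_yr, c.rate_se_umol_cm2_yr)
        fluxes.append(f)
        per_site.append(
            {
                "name": s.name,
                "seep_area_m2": s.seep_area_m2,
                "rock_area_m2": s.rock_area_m2,
                "rock_fraction_pct": s.rock_fraction_pct,
                "flux_mol_yr": f.flux,
                "flux_se_mol_yr": f.flux_se,
            }
        )
        log.info("%s: %.3g (±%.3g) mol CaCO3/yr", s.name, f.flux, f.flux_se)
    precip = PrecipitationFlux(
        central=c.precip_central_mol_yr,
        low=c.precip_low_mol_yr,
        high=c.precip_high_mol_yr,
    )
    est = summarize_global(
        fluxes, c.n_seeps, precip, se_rule=config.options.se_rule, constants=constants
    )
    log.info(
        "global: %.3g (±%.3g) mol C/yr = %.3g kg C/yr; lability %.2f%% (%.2f-%.2f%%)",
        est.global_flux, est.global_flux_se, est.global_mass_kg,
        est.lability_pct, *est.lability_range,
    )
    payload = {
        "sites": per_site,
        "global": {
            "n_seeps": est.n_seeps,
            "global_flux_mol_yr": est.global_flux,
            "global_flux_se_mol_yr": est.global_flux_se,
            "global_mass_kg_yr": est.global_mass_kg,
            "lability_pct": est.lability_pct,
            "lability_range_pct": list(est.lability_range),
        },
    }
    out = Path(cfg.out)
    out.parent.mkdir(parents=True, exist_ok=True)
    with open(out, "w") as fh:
        json.dump(_stamp(config, payload), fh, indent=1)
    entry["outputs"]["global"] = str(out)
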