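"""End-to-end QA workflow: from dose grid and film scan to a gamma report.

``run_qa`` executes the full verification chain -- read the calculated
3D dose, build the calibration curve, convert the scanned film to dose,
resample the calculation onto the film surface (or an orthogonal
plane), register, run the gamma analysis, extract radial profiles and
isodose contours -- and returns one machine-readable report.  Every
stage logs its inputs and exclusion counts; any stage error aborts with
the stage name and cause.

Inputs come from a single configuration mapping (JSON/YAML-friendly):
file-based (DICOM RT Dose + TIFF scans + calibration CSV) or fully
synthetic (an analytic plan spec plus a virtual-film perturbation
model), in any combination.
"""

from __future__ import annotations

import logging
import math
import time

import numpy as np

from . import compare, film, resample, stats, synthetic
from .dose_io import DoseGrid, PlanarDoseMap, read_rtdose
from .geometry import SpiralGeometry

__all__ = ["PipelineError", "geometry_from_config", "run_qa",
           "run_grid_size_experiment"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def _stage(name: str, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        out = fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise PipelineError(f"stage '{name}' failed: {exc}") from exc
    log.info("stage %s done in %.3f s", name, time.perf_counter() - t0)
    return out


def geometry_from_config(cfg: dict | None) -> SpiralGeometry:
    """Build a SpiralGeometry from configuration keys (mm for film sizes)."""
    cfg = cfg or {}
    return SpiralGeometry(
        a=cfg.get("a_cm_per_rad", 0.5129),
        theta_min=cfg.get("theta_min_rad", math.pi / 3.0),
        film_width=cfg.get("film_width_mm", 130.0) / 10.0,
        film_arc_length=cfg.get("film_arc_length_mm", 254.0) / 10.0,
        handedness=cfg.get("handedness", "counterclockwise"),
    )


def _gamma_params(cfg: dict | None) -> compare.GammaParams:
    cfg = cfg or {}
    return compare.GammaParams(
        dta=cfg.get("dta_mm", 3.0) / 10.0,
        dd=cfg.get("dd_pct", 3.0) / 100.0,
        normalization=cfg.get("normalization", "local"),
        threshold=cfg.get("threshold_pct", 50.0) / 100.0,
        global_reference=cfg.get("global_reference", "plane_max"),
        prescribed_dose=cfg.get("prescribed_dose_cGy"),
    )


def _load_calculated_grid(cfg: dict) -> tuple[DoseGrid, object | None]:
    """Returns (grid, analytic_fn or None)."""
    if "rtdose" in cfg:
        return read_rtdose(cfg["rtdose"]), None
    syn = cfg["synthetic"]
    spec = synthetic.FieldSpec(
        kind=syn.get("kind", "single_field"),
        field_size=tuple(syn.get("field_size_cm", (6.0, 6.0))),
        central_dose=syn.get("central_dose_cGy", 200.0),
        penumbra_sigma=syn.get("penumbra_sigma_cm", 0.4),
        attenuation_mu=syn.get("attenuation_mu_per_cm", 0.04),
        target_center=tuple(syn.get("target_center_cm", (0.0, 0.0, 0.0))),
        target_radius=syn.get("target_radius_cm", 2.5),
        n_beams=syn.get("n_beams", 72),
    )
    fn = synthetic.dose_function(spec)
    grid = synthetic.sample_to_grid(fn, syn.get("spacing_cm", 0.2))
    return grid, fn


def _calculated_plane(grid, geom, plane, pitch) -> PlanarDoseMap:
    if plane == "spiral":
        return resample.resample_spiral(grid, geom, pitch)
    return resample.extract_orthogonal_plane(grid, plane, 0.0, pitch)


def _measured_map(cfg: dict, calc_plane: PlanarDoseMap, fn,
                  report: dict) -> PlanarDoseMap:
    """Measured dose map from scans+calibration, or a virtual measurement."""
    if "scan" in cfg:
        points = film.read_calibration_table(cfg["calibration_table"])
        curve = film.fit_calibration(points)
        scan = film.read_scan(cfg["scan"], dpi=cfg.get("dpi"))
        blank = cfg.get("blank")
        if isinstance(blank, str):
            blank = film.read_scan(blank, dpi=cfg.get("dpi"))
        elif blank is None:
            blank = curve.unexposed_value
        od = film.net_od(scan, blank)
        report["calibration"] = {
            "b": curve.b, "c": curve.c, "n": curve.n,
            "fit_residual_cGy": curve.fit_residual,
        }
        return film.od_to_dose(od, curve, scan.pitch_cm)

    # virtual measurement: true dose on the plane -> film -> scan -> dose
    syn = cfg.get("synthetic", {})
    if fn is None:
        raise ValueError("synthetic measurement requires a synthetic plan")
    dpi = syn.get("dpi", 72.0)
    pitch = 2.54 / dpi
    if not math.isclose(pitch, calc_plane.pitch[0], rel_tol=1e-9):
        raise ValueError("synthetic measurement dpi must match resample pitch")
    perturb = synthetic.PerturbationSpec(
        shift=tuple(syn.get("shift_cm", (0.0, 0.0))),
        dose_scale=syn.get("dose_scale", 1.0),
        noise_sd=syn.get("noise_pct", 0.0) / 100.0,
        stripe_amplitude=syn.get("stripe_amplitude", 0.0),
        stripe_period=syn.get("stripe_period_cm", 1.0),
        seed=syn.get("seed"),
    )
    true_plane = _analytic_plane(fn, cfg["_geom"], cfg["_plane"], pitch,
                                 calc_plane)
    curve = synthetic.default_calibration_curve()
    _, table = synthetic.make_calibration_set(curve, dpi=dpi)
    fitted = film.fit_calibration(
        list(zip(table["dose_cGy"], table["netOD"]))
    )
    scan = synthetic.synthesize_film(true_plane, curve, perturb, dpi=dpi)
    od = film.net_od(scan, curve.unexposed_value)
    report["calibration"] = {
        "b": fitted.b, "c": fitted.c, "n": fitted.n,
        "fit_residual_cGy": fitted.fit_residual,
    }
    measured = film.od_to_dose(od, fitted, scan.pitch_cm)
    measured.origin_uv = true_plane.origin_uv
    measured.plane_label = true_plane.plane_label
    return measured


def _analytic_plane(fn, geom, plane, pitch, calc_plane) -> PlanarDoseMap:
    if plane == "spiral":
        return synthetic.analytic_spiral_map(fn, geom, pitch)
    uu, vv = np.meshgrid(calc_plane.u_coords(), calc_plane.v_coords())
    au, av, an = resample._PLANE_AXES[plane]
    pts = np.zeros(uu.shape + (3,))
    pts[..., au] = uu
    pts[..., av] = vv
    return PlanarDoseMap(
        values=fn(pts.reshape(-1, 3)).reshape(uu.shape),
        pitch=calc_plane.pitch, origin_uv=calc_plane.origin_uv,
        plane_label=plane,
    )


def run_qa(config: dict) -> dict:
    """Run the full film-QA workflow described by ``config``.

    Returns a report dict with the gamma pass rate, analysis counts,
    gamma histogram, per-angle profile RMS differences, contour counts
    and all parameters used.
    """
    report: dict = {"stages": []}
    geom = _stage("geometry", geometry_from_config, config.get("geometry"))
    plane = config.get("plane", "spiral")
    pitch = config.get("pitch_mm", 10 * resample.FILM_SCAN_PITCH_CM) / 10.0
    params = _gamma_params(config.get("gamma"))

    grid, fn = _stage("read-calculated", _load_calculated_grid,
                      config["calculated"])
    calc_plane = _stage("resample", _calculated_plane, grid, geom, plane, pitch)

    meas_cfg = dict(config["measured"])
    meas_cfg["_geom"] = geom
    meas_cfg["_plane"] = plane
    measured = _stage("film-to-dose", _measured_map, meas_cfg, calc_plane, fn,
                      report)

    reg = config.get("registration", {})
    measured = _stage(
        "register", film.register_film, measured,
        (reg.get("flip_u", False), reg.get("flip_v", False)),
        tuple(reg.get("offset_cm", (0.0, 0.0))),
    )

    result = _stage("gamma", compare.gamma_map, measured, calc_plane, params)
    profiles = _stage("profiles", compare.radial_profiles, measured, calc_plane,
                      config.get("profile_angle_step_deg", 12.0))
    contours_m = _stage("contours", compare.isodose_contours, measured)
    contours_c = _stage("contours", compare.isodose_contours, calc_plane)

    finite = result.gamma[np.isfinite(result.gamma)]
    hist, edges = np.histogram(finite, bins=20, range=(0.0, 2.0))
    profile_rms = [
        {
            "angle_deg": p["angle_deg"],
            "rms_diff": float(np.sqrt(np.nanmean(
                (p["measured"] - p["calculated"]) ** 2))),
        }
        for p in profiles
    ]
    report.update(
        {
            "plane": plane,
            "pitch_cm": pitch,
            "gamma_params": {
                "dta_cm": params.dta,
                "dd": params.dd,
                "normalization": params.normalization,
                "threshold": params.threshold,
            },
            "pass_rate": result.pass_rate,
            "n_analyzed": result.n_analyzed,
            "n_passing": result.n_passing,
            "n_excluded_invalid_calc": result.n_excluded_invalid_calc,
            "gamma_mean": float(finite.mean()),
            "gamma_histogram": {
                "edges": edges.tolist(),
                "counts": hist.tolist(),
            },
            "profile_rms_diff": profile_rms,
            "n_contours_measured": len(contours_m),
            "n_contours_calculated": len(contours_c),
        }
    )
    return report


def run_grid_size_experiment(config: dict) -> dict:
    """Per-plan gamma pass rates at two calculation grid sizes.

    For each of ``n_plans`` seeded VMAT-like plans the analytic truth on
    the spiral plane stands in for the measurement, and the calculation
    is the analytic field sampled onto 3D grids at the two spacings and
    resampled back onto the film surface.  Reports paired pass rates and
    the exact Wilcoxon comparison.
    """
    geom = geometry_from_config(config.get("geometry"))
    n_plans = config.get("n_plans", 5)
    seed = config.get("seed", 1)
    spacings = config.get("spacings_cm", (0.2, 0.1))
    pitch = config.get("pitch_mm", 1.0) / 10.0
    params = _gamma_params(config.get("gamma"))
    rng = np.random.default_rng(seed)

    rates: dict[float, list[float]] = {s: [] for s in spacings}
    plans = []
    for k in range(n_plans):
        spec = synthetic.FieldSpec(
            kind="vmat_like",
            target_center=(
                float(rng.uniform(-1.0, 1.0)),
                float(rng.uniform(-1.0, 1.0)),
                float(rng.uniform(-0.5, 0.5)),
            ),
            target_radius=float(rng.uniform(2.0, 3.0)),
            field_size=(float(rng.uniform(5.0, 7.0)),) * 2,
            n_beams=config.get("n_beams", 72),
        )
        fn = synthetic.dose_function(spec)
        truth = synthetic.analytic_spiral_map(fn, geom, pitch)
        plan = {"plan": k, "target_center_cm": spec.target_center}
        for s in spacings:
            grid = synthetic.sample_to_grid(fn, s)
            calc = resample.resample_spiral(grid, geom, pitch)
            res = compare.gamma_map(truth, calc, params)
            rates[s].append(res.pass_rate)
            plan[f"pass_rate_{s*10:g}mm"] = res.pass_rate
            plan[f"max_dev_cGy_{s*10:g}mm"] = float(
                np.nanmax(np.abs(calc.values - truth.values))
            )
        plans.append(plan)

    coarse, fine = max(spacings), min(spacings)
    comparison = stats.compare_conditions(rates[coarse], rates[fine])
    return {
        "n_plans": n_plans,
        "seed": seed,
        "pitch_cm": pitch,
        "spacings_cm": list(spacings),
        "plans": plans,
        "pass_rates": {f"{s*10:g}mm": rates[s] for s in spacings},
        "comparison_coarse_vs_fine": comparison,
    }
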