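"""Synthetic dose engines and virtual film scans.

Everything the pipeline needs can be generated here with no external
data: smooth analytic 3D dose distributions (a single rectangular field
and a VMAT-like rotational accumulation), virtual film scans produced by
pushing a planar dose map through the inverse calibration response, and
the ten-level calibration series.

The dose engines are analytic rather than Monte Carlo: the lateral
profile is a pair of error-function penumbra edges and the depth
behaviour an exponential attenuation, giving closed-form check points
(50% of the local axis dose exactly at the field edge, mirror symmetry,
exact target-center normalization).  A VMAT-like distribution is the
superposition of many copies of the single-field kernel rotated
uniformly over 360 degrees about the phantom axis and aimed at the
target -- rotationally near-symmetric for many beams, like an
accumulated arc delivery.  Perturbations (spatial shift, dose scaling,
multiplicative noise, axial stripes) produce controlled-error fixtures;
every stochastic element draws from an explicit seed, never global
state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates
from scipy.special import erf

from .dose_io import DoseGrid, PlanarDoseMap
from .film import CalibrationCurve, FilmScan
from .geometry import SpiralGeometry, film_to_phantom
from .resample import _raster

__all__ = [
    "CALIBRATION_DOSES_CGY",
    "PHANTOM_RADIUS_CM",
    "FieldSpec",
    "PerturbationSpec",
    "default_calibration_curve",
    "single_field_function",
    "vmat_like_function",
    "sample_to_grid",
    "single_field_dose",
    "vmat_like_dose",
    "analytic_spiral_map",
    "synthesize_film",
    "make_calibration_set",
]

#: the standard ten-level calibration dose series, cGy (0 to 400 MU)
CALIBRATION_DOSES_CGY = (
    0.0, 2.4, 4.0, 8.0, 19.9, 39.8, 79.6, 159.2, 238.8, 318.3,
)

#: synthetic water-cylinder radius, cm (> the spiral's outer radius ~5.1 cm)
PHANTOM_RADIUS_CM = 6.0


@dataclass(frozen=True)
class FieldSpec:
    """Analytic beam/plan description.

    central_dose defaults to 200 cGy, a typical single fraction of a
    74 Gy / 37 fraction prostate prescription.
    """

    kind: str = "single_field"  # or "vmat_like"
    field_size: tuple[float, float] = (6.0, 6.0)  # (lateral, axial) cm
    central_dose: float = 200.0  # cGy
    penumbra_sigma: float = 0.4  # cm
    attenuation_mu: float = 0.04  # 1/cm
    target_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    target_radius: float = 2.5  # cm
    n_beams: int = 72
    beam_weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("single_field", "vmat_like"):
            raise ValueError(f"unknown field kind {self.kind!r}")
        if min(self.field_size) <= 0 or self.central_dose <= 0:
            raise ValueError("field size and central dose must be positive")
        if self.penumbra_sigma <= 0 or self.target_radius <= 0:
            raise ValueError("penumbra sigma and target radius must be positive")
        if self.n_beams < 1:
            raise ValueError("n_beams must be >= 1")
        if self.beam_weights is not None and len(self.beam_weights) != self.n_beams:
            raise ValueError("beam_weights length must equal n_beams")


@dataclass(frozen=True)
class PerturbationSpec:
    """Controlled measurement-error model for virtual films."""

    shift: tuple[float, float] = (0.0, 0.0)  # (du, dv) cm
    dose_scale: float = 1.0  # multiplicative
    noise_sd: float = 0.0  # fraction of local dose
    stripe_amplitude: float = 0.0  # fraction, axial stripes
    stripe_period: float = 1.0  # cm
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.noise_sd > 0 and self.seed is None:
            raise ValueError("a seed is mandatory whenever noise_sd > 0")
        if self.dose_scale <= 0:
            raise ValueError("dose_scale must be positive")


def default_calibration_curve() -> CalibrationCurve:
    """The generating response used throughout the synthetic studies.

    D = 300*netOD + 500*netOD**2.5 spans the 0-318.3 cGy
    calibration series with netOD reaching ~0.55, in the range typical
    of red-channel EBT2 readings.
    """
    b, c, n = 300.0, 500.0, 2.5
    curve = CalibrationCurve(
        control_points=[], b=b, c=c, n=n, fit_residual=0.0,
        valid_range=(0.0, 0.75), unexposed_value=40000.0,
    )
    pts = [(d, curve.net_od_from_dose(d)) for d in CALIBRATION_DOSES_CGY]
    curve.control_points = pts
    return curve


# ---------------------------------------------------------------------------
# Analytic dose engines


def _edge_profile(x, half_width, sigma):
    s = sigma * math.sqrt(2.0)
    return 0.5 * (erf((half_width - x) / s) + erf((half_width + x) / s))


def single_field_function(spec: FieldSpec):
    """Closed-form dose (cGy) of a single field at gantry 0 (beam along -y).

    D(x, y, z) = D0 * P(x) * P(z) * exp(-mu * depth), with P a pair of
    erf penumbra edges at +-field/2 and depth measured from the entry
    surface at y = +R (so the on-axis entry dose is D0).
    """
    wx, wz = spec.field_size[0] / 2.0, spec.field_size[1] / 2.0

    def dose(pts):
        p = np.asarray(pts, dtype=float)
        x, y, z = p[..., 0], p[..., 1], p[..., 2]
        depth = np.maximum(PHANTOM_RADIUS_CM - y, 0.0)
        return (
            spec.central_dose
            * _edge_profile(x, wx, spec.penumbra_sigma)
            * _edge_profile(z, wz, spec.penumbra_sigma)
            * np.exp(-spec.attenuation_mu * depth)
        )

    return dose


def vmat_like_function(spec: FieldSpec):
    """Rotational accumulation of the single-field kernel.

    n_beams copies of the kernel at uniform gantry angles over 360
    degrees, each aimed at ``target_center``, normalised so the dose at
    the target center equals ``central_dose``.
    """
    wx, wz = spec.field_size[0] / 2.0, spec.field_size[1] / 2.0
    c = np.asarray(spec.target_center, dtype=float)
    phis = 2.0 * np.pi * np.arange(spec.n_beams) / spec.n_beams
    weights = (
        np.asarray(spec.beam_weights, dtype=float)
        if spec.beam_weights is not None
        else np.ones(spec.n_beams)
    )
    # beam travel direction and in-plane lateral unit, per gantry angle
    u_dir = np.stack([np.sin(phis), -np.cos(phis)], axis=1)
    lat_dir = np.stack([np.cos(phis), np.sin(phis)], axis=1)

    def raw(pts):
        p = np.asarray(pts, dtype=float)
        xy = p[..., :2] - c[:2]
        z = p[..., 2] - c[2]
        lateral = xy @ lat_dir.T  # (..., n_beams)
        along = p[..., :2] @ u_dir.T
        depth = np.maximum(along + PHANTOM_RADIUS_CM, 0.0)
        contrib = (
            _edge_profile(lateral, wx, spec.penumbra_sigma)
            * _edge_profile(z[..., None], wz, spec.penumbra_sigma)
            * np.exp(-spec.attenuation_mu * depth)
        )
        return contrib @ weights

    norm = spec.central_dose / raw(c[None, :])[0]

    def dose(pts):
        return norm * raw(pts)

    return dose


def dose_function(spec: FieldSpec):
    """The analytic dose function matching ``spec.kind``."""
    if spec.kind == "single_field":
        return single_field_function(spec)
    return vmat_like_function(spec)


def sample_to_grid(
    fn,
    spacing: float,
    half_extent_xy: float = PHANTOM_RADIUS_CM + 0.5,
    half_extent_z: float = 7.0,
) -> DoseGrid:
    """Sample an analytic dose function onto a regular axis-aligned grid.

    The grid is centred on the isocenter and covers the phantom
    cylinder, emulating a TPS export at the requested calculation grid
    size (0.1 or 0.2 cm typical).
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    nxy = int(round(2 * half_extent_xy / spacing)) + 1
    nz = int(round(2 * half_extent_z / spacing)) + 1
    xs = -half_extent_xy + spacing * np.arange(nxy)
    zs = -half_extent_z + spacing * np.arange(nz)
    xx, yy, zz = np.meshgrid(xs, xs, zs, indexing="ij")
    pts = np.stack([xx, yy, zz], axis=-1).reshape(-1, 3)
    # chunked evaluation keeps the per-beam intermediates of the VMAT-like
    # engine at a modest memory footprint
    chunk = 1 << 16
    values = np.concatenate(
        [fn(pts[i : i + chunk]) for i in range(0, pts.shape[0], chunk)]
    ).reshape(xx.shape)
    return DoseGrid(
        values=values,
        origin=np.array([xs[0], xs[0], zs[0]]),
        spacing=np.array([spacing, spacing, spacing]),
    )


def single_field_dose(spec: FieldSpec, spacing: float) -> DoseGrid:
    """Single-field analytic dose sampled onto a grid (see sample_to_grid)."""
    return sample_to_grid(single_field_function(spec), spacing)


def vmat_like_dose(spec: FieldSpec, spacing: float) -> DoseGrid:
    """VMAT-like analytic dose sampled onto a grid (see sample_to_grid)."""
    return sample_to_grid(vmat_like_function(spec), spacing)


def analytic_spiral_map(
    fn, geom: SpiralGeometry, pitch: float
) -> PlanarDoseMap:
    """Ground-truth dose on the spiral film surface, directly from the
    analytic function (no grid, no interpolation)."""
    u = _raster(geom.film_arc_length, pitch)
    v = _raster(geom.film_width, pitch)
    uu, vv = np.meshgrid(u, v)
    pts = film_to_phantom(uu.ravel(), vv.ravel(), geom)
    return PlanarDoseMap(
        values=fn(pts).reshape(vv.shape),
        pitch=(pitch, pitch),
        origin_uv=(u[0], v[0]),
        plane_label="spiral",
    )


# ---------------------------------------------------------------------------
# Virtual films


def _apply_perturbations(
    values: np.ndarray, pitch: tuple[float, float], perturb: PerturbationSpec,
    v_coords: np.ndarray,
) -> np.ndarray:
    out = values * perturb.dose_scale
    du, dv = perturb.shift
    if du != 0.0 or dv != 0.0:
        nv, nu = out.shape
        jj, ii = np.meshgrid(np.arange(nu), np.arange(nv))
        coords = np.stack([ii - dv / pitch[1], jj - du / pitch[0]])
        out = map_coordinates(out, coords, order=1, mode="nearest")
    if perturb.stripe_amplitude:
        stripe = 1.0 + perturb.stripe_amplitude * np.sin(
            2.0 * np.pi * v_coords / perturb.stripe_period
        )
        out = out * stripe[:, None]
    if perturb.noise_sd > 0:
        rng = np.random.default_rng(perturb.seed)
        out = out * rng.normal(1.0, perturb.noise_sd, size=out.shape)
    return np.clip(out, 0.0, None)


def synthesize_film(
    true_dose: PlanarDoseMap,
    curve: CalibrationCurve,
    perturb: PerturbationSpec | None = None,
    dpi: float = 72.0,
) -> FilmScan:
    """Virtual film measurement of a planar dose map.

    Perturbations are applied to the dose, the dose is pushed through
    the inverse calibration response to netOD, converted to a red-channel
    transmission value I = I0 * 10**(-netOD), and quantised to 16 bits.
    Deterministic given the perturbation seed.  The input raster must be
    at the scan pitch (2.54/dpi cm).
    """
    perturb = perturb or PerturbationSpec()
    pitch = 2.54 / dpi
    if not (
        math.isclose(true_dose.pitch[0], pitch, rel_tol=1e-9)
        and math.isclose(true_dose.pitch[1], pitch, rel_tol=1e-9)
    ):
        raise ValueError(
            f"dose-map pitch {true_dose.pitch} does not match {dpi} dpi scan pitch"
        )
    values = np.nan_to_num(true_dose.values, nan=0.0)
    values = _apply_perturbations(
        values, true_dose.pitch, perturb, true_dose.v_coords()
    )
    max_dose = curve.dose(curve.valid_range[1])
    values = np.clip(values, 0.0, max_dose)
    od = curve.net_od_from_dose(values)
    red = np.clip(
        np.round(curve.unexposed_value * np.power(10.0, -od)), 0, 65535
    ).astype(np.uint16)
    return FilmScan(red_channel=red, dpi=dpi)


def make_calibration_set(
    curve: CalibrationCurve,
    doses=CALIBRATION_DOSES_CGY,
    dpi: float = 72.0,
    piece_size_cm: tuple[float, float] = (2.0, 2.0),
):
    """Uniformly exposed virtual calibration pieces plus the paired table.

    One uniform film piece per dose level (default: the standard
    ten-level series) and a DataFrame with columns dose_cGy, netOD and
    red_value; netOD in the table comes from exact inversion of the
    generating curve.
    """
    doses = [float(d) for d in doses]
    if any(d < 0 for d in doses) or 0.0 not in doses:
        raise ValueError("dose series must be non-negative and include 0")
    pitch = 2.54 / dpi
    n_u = max(2, int(round(piece_size_cm[0] / pitch)))
    n_v = max(2, int(round(piece_size_cm[1] / pitch)))
    scans, rows = [], []
    for d in doses:
        od = curve.net_od_from_dose(d)
        red = int(np.clip(round(curve.unexposed_value * 10.0 ** (-od)), 0, 65535))
        scans.append(
            FilmScan(red_channel=np.full((n_v, n_u), red, dtype=np.uint16),
                     dpi=dpi)
        )
        rows.append({"dose_cGy": d, "netOD": od, "red_value": red})
    return scans, pd.DataFrame(rows)
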