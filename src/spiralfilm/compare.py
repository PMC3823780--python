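"""Measured-vs-calculated comparison: gamma index, profiles, isodose contours.

The gamma index combines a dose-difference criterion (dd, a fraction of
a reference dose) with a distance-to-agreement criterion (dta, cm).  For
a measured pixel m the index is

    gamma(m) = min over calculated samples c of
               sqrt( |r_c - r_m|^2 / dta^2  +  (D_c - D_m)^2 / (dd * D_ref)^2 )

and the pixel passes when gamma <= 1.  With *local* normalization
D_ref is the measured dose at m itself ("3% relative to each measured
dose"); with *global* (VanDyk) normalization D_ref is a fixed plane-wide
reference, either the measured plane maximum or a prescribed dose.
Pixels below a dose threshold (default 50% of the measured plane
maximum) are excluded from the analysis.

The measured distribution is the reference and the calculated
distribution is searched; before the search the calculated map is
densified by bilinear interpolation to a sub-pixel step (default dta/10)
so the minimisation is not limited to the raster.  The optimised search
restricts candidates to a radius (default 3*dta) around each pixel and
provably returns the global minimum: any candidate farther than
``gamma_found * dta`` cannot beat the incumbent because its distance
term alone exceeds it, and the search radius is expanded whenever that
bound is not yet met.  ``gamma_brute_force`` performs the exhaustive
scan over every densified sample and serves as the test oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from skimage import measure

from .dose_io import PlanarDoseMap

__all__ = [
    "GammaParams",
    "GammaResult",
    "gamma_map",
    "gamma_brute_force",
    "pass_rate_summary",
    "radial_profiles",
    "isodose_contours",
    "sample_map",
]

#: numerical slack on the gamma <= 1 pass decision (pure fp round-off)
_PASS_EPS = 1e-9


@dataclass(frozen=True)
class GammaParams:
    """Gamma-analysis criteria.

    dta in cm (default 0.3 = 3 mm), dd as a fraction (default 0.03 = 3%),
    threshold as a fraction of the measured plane maximum (default 0.5).
    """

    dta: float = 0.3
    dd: float = 0.03
    normalization: str = "local"  # or "global"
    threshold: float = 0.5
    global_reference: str = "plane_max"  # or "prescribed_dose"
    prescribed_dose: float | None = None
    search_radius: float | None = None  # default 3*dta
    search_step: float | None = None  # default dta/10

    def __post_init__(self) -> None:
        if self.dta <= 0:
            raise ValueError("dta must be positive")
        if not 0 < self.dd < 1:
            raise ValueError("dd must be a fraction in (0, 1)")
        if not 0 <= self.threshold < 1:
            raise ValueError("threshold must be a fraction in [0, 1)")
        if self.normalization not in ("local", "global"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.global_reference not in ("plane_max", "prescribed_dose"):
            raise ValueError(f"unknown global_reference {self.global_reference!r}")
        if self.step > self.dta / 3 + 1e-12:
            raise ValueError("search_step must be <= dta/3")

    @property
    def radius(self) -> float:
        return self.search_radius if self.search_radius is not None else 3 * self.dta

    @property
    def step(self) -> float:
        return self.search_step if self.search_step is not None else self.dta / 10


@dataclass
class GammaResult:
    """Per-pixel gamma map plus the pass-rate statistic."""

    gamma: np.ndarray  # NaN outside the analysis mask
    mask: np.ndarray
    params: GammaParams
    n_analyzed: int
    n_passing: int
    n_excluded_invalid_calc: int = 0
    notes: dict = field(default_factory=dict)

    @property
    def pass_rate(self) -> float:
        """Percentage of analysed pixels with gamma <= 1."""
        if self.n_analyzed == 0:
            return float("nan")
        return 100.0 * self.n_passing / self.n_analyzed


def sample_map(dmap: PlanarDoseMap, u, v) -> np.ndarray:
    """Bilinear sample of a planar map at (u, v) cm; NaN outside."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    col = (u - dmap.origin_uv[0]) / dmap.pitch[0]
    row = (v - dmap.origin_uv[1]) / dmap.pitch[1]
    # forgive pure round-off at the raster boundary
    eps = 1e-9
    col = np.where((col > -eps) & (col < 0), 0.0, col)
    row = np.where((row > -eps) & (row < 0), 0.0, row)
    nr, nc = dmap.values.shape
    col = np.where((col > nc - 1) & (col < nc - 1 + eps), nc - 1, col)
    row = np.where((row > nr - 1) & (row < nr - 1 + eps), nr - 1, row)
    return map_coordinates(
        dmap.values, np.stack([row, col]), order=1, mode="constant", cval=np.nan
    )


def _same_raster(a: PlanarDoseMap, b: PlanarDoseMap) -> bool:
    return (
        a.values.shape == b.values.shape
        and np.allclose(a.pitch, b.pitch, rtol=0, atol=1e-12)
        and np.allclose(a.origin_uv, b.origin_uv, rtol=0, atol=1e-9)
    )


def _to_raster_of(src: PlanarDoseMap, ref: PlanarDoseMap) -> PlanarDoseMap:
    uu, vv = np.meshgrid(ref.u_coords(), ref.v_coords())
    return PlanarDoseMap(
        values=sample_map(src, uu, vv),
        pitch=ref.pitch,
        origin_uv=ref.origin_uv,
        plane_label=src.plane_label,
    )


def _densify(calc: PlanarDoseMap, step: float):
    """Bilinearly refine the calculated map so nodes fall every <= step cm.

    The refinement factor per axis is an integer, so every original
    pixel center remains a node; returns (fine values, (fv, fu) fine
    pitch, (kv, ku) factors).  NaN pixels propagate to the fine cells
    that touch them.
    """
    nv, nu = calc.values.shape
    ku = max(1, math.ceil(calc.pitch[0] / step - 1e-12))
    kv = max(1, math.ceil(calc.pitch[1] / step - 1e-12))
    fu = calc.pitch[0] / ku
    fv = calc.pitch[1] / kv
    rows = np.arange((nv - 1) * kv + 1) / kv if nv > 1 else np.zeros(1)
    cols = np.arange((nu - 1) * ku + 1) / ku if nu > 1 else np.zeros(1)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    fine = map_coordinates(
        calc.values, np.stack([rr, cc]), order=1, mode="constant", cval=np.nan
    )
    return fine, (fv, fu), (kv, ku)


def _prepare(measured: PlanarDoseMap, calculated: PlanarDoseMap,
             params: GammaParams):
    if not _same_raster(measured, calculated):
        calculated = _to_raster_of(calculated, measured)
    dm = measured.values
    plane_max = np.nanmax(dm)
    valid_m = np.isfinite(dm)
    valid_c = np.isfinite(calculated.values)
    mask = valid_m & (dm >= params.threshold * plane_max) & valid_c
    n_excluded = int(np.sum(valid_m & (dm >= params.threshold * plane_max)
                            & ~valid_c))
    if not mask.any():
        raise ValueError("threshold excludes all pixels")
    if params.normalization == "local":
        dref = dm
    elif params.global_reference == "prescribed_dose":
        if params.prescribed_dose is None:
            raise ValueError("global_reference='prescribed_dose' needs a value")
        dref = np.full_like(dm, params.prescribed_dose)
    else:
        dref = np.full_like(dm, plane_max)
    return calculated, mask, dref, n_excluded


def gamma_map(
    measured: PlanarDoseMap,
    calculated: PlanarDoseMap,
    params: GammaParams | None = None,
) -> GammaResult:
    """Optimised gamma analysis of a calculated map against a measured map.

    Maps on different rasters are first resampled to the measured
    raster.  Equals :func:`gamma_brute_force` (the exhaustive oracle) up
    to floating-point round-off.
    """
    params = params or GammaParams()
    calculated, mask, dref, n_excl = _prepare(measured, calculated, params)
    dm = measured.values
    fine, (fv, fu), (kv, ku) = _densify(calculated, params.step)
    nv, nu = dm.shape
    nfv, nfu = fine.shape

    dd_denom = params.dd * dref
    gamma2 = np.full(dm.shape, np.inf)
    radius = params.radius
    diag = math.hypot((nfv - 1) * fv, (nfu - 1) * fu)
    todo = mask.copy()
    while True:
        gamma2 = np.minimum(
            gamma2,
            _min_gamma2_within(dm, dd_denom, todo, fine, fv, fu, kv, ku, radius,
                               params.dta),
        )
        # a candidate beyond r has gamma > r/dta from its distance term alone,
        # so pixels with sqrt(gamma2) <= r/dta already hold the global minimum
        unresolved = todo & (gamma2 > (radius / params.dta) ** 2 * (1 + 1e-12))
        if radius >= diag or not unresolved.any():
            break
        radius = min(max(2 * radius, params.dta * math.sqrt(
            np.max(gamma2[unresolved]))), diag)
        todo = unresolved

    gamma = np.sqrt(gamma2)
    gamma = np.where(mask, gamma, np.nan)
    n_analyzed = int(mask.sum())
    n_passing = int(np.sum(gamma[mask] <= 1.0 + _PASS_EPS))
    return GammaResult(
        gamma=gamma,
        mask=mask,
        params=params,
        n_analyzed=n_analyzed,
        n_passing=n_passing,
        n_excluded_invalid_calc=n_excl,
    )


def _min_gamma2_within(dm, dd_denom, mask, fine, fv, fu, kv, ku, radius, dta):
    """Min gamma^2 over densified candidates within ``radius`` of each pixel."""
    nv, nu = dm.shape
    mi = math.floor(radius / fv + 1e-12)
    mj = math.floor(radius / fu + 1e-12)
    pad_v, pad_u = mi, mj
    padded = np.pad(fine, ((pad_v, pad_v), (pad_u, pad_u)), constant_values=np.nan)
    nfv = (nv - 1) * kv + 1
    nfu = (nu - 1) * ku + 1
    # offsets sorted by spatial penalty: cheap candidates first
    oi, oj = np.meshgrid(np.arange(-mi, mi + 1), np.arange(-mj, mj + 1),
                         indexing="ij")
    d2 = (oi * fv) ** 2 + (oj * fu) ** 2
    keep = d2 <= radius**2 * (1 + 1e-12)
    order = np.argsort(d2[keep], kind="stable")
    oi_l, oj_l, d2_l = oi[keep][order], oj[keep][order], d2[keep][order]

    gamma2 = np.full(dm.shape, np.inf)
    dmv = dm[mask]
    denom = dd_denom[mask]
    g = np.full(dmv.shape, np.inf)
    rows, cols = np.nonzero(mask)
    for o_i, o_j, dist2 in zip(oi_l, oj_l, d2_l):
        spatial = dist2 / dta**2
        if g.size and spatial >= g.max():
            break  # all remaining offsets are spatially dominated
        cand = padded[
            pad_v + o_i : pad_v + o_i + nfv : kv,
            pad_u + o_j : pad_u + o_j + nfu : ku,
        ][rows, cols]
        with np.errstate(invalid="ignore"):
            trial = spatial + ((cand - dmv) / denom) ** 2
        g = np.where(np.isnan(trial), g, np.minimum(g, trial))
    gamma2[mask] = g
    return gamma2


def gamma_brute_force(
    measured: PlanarDoseMap,
    calculated: PlanarDoseMap,
    params: GammaParams | None = None,
    chunk: int = 512,
) -> GammaResult:
    """Exhaustive gamma analysis: every densified calculated sample is
    scanned for every analysed pixel, with no pruning.

    The independent oracle for :func:`gamma_map`; quadratic cost, meant
    for modest map sizes and tests.
    """
    params = params or GammaParams()
    calculated, mask, dref, n_excl = _prepare(measured, calculated, params)
    dm = measured.values
    fine, (fv, fu), (kv, ku) = _densify(calculated, params.step)
    nfv, nfu = fine.shape
    # absolute fine-sample coordinates (cm), flattened over finite samples
    u_f = calculated.origin_uv[0] + np.arange(nfu) * fu
    v_f = calculated.origin_uv[1] + np.arange(nfv) * fv
    uu_f, vv_f = np.meshgrid(u_f, v_f)
    finite = np.isfinite(fine)
    cu, cv, cd = uu_f[finite], vv_f[finite], fine[finite]

    rows, cols = np.nonzero(mask)
    mu = measured.origin_uv[0] + cols * measured.pitch[0]
    mv = measured.origin_uv[1] + rows * measured.pitch[1]
    dmv = dm[rows, cols]
    denom = params.dd * dref[rows, cols]

    gmin = np.full(dmv.shape, np.inf)
    inv_dta2 = 1.0 / params.dta**2
    for start in range(0, dmv.size, chunk):
        sl = slice(start, start + chunk)
        du = cu[None, :] - mu[sl, None]
        np.multiply(du, du, out=du)
        dv = cv[None, :] - mv[sl, None]
        np.multiply(dv, dv, out=dv)
        du += dv
        du *= inv_dta2
        dv = cd[None, :] - dmv[sl, None]
        dv /= denom[sl, None]
        np.multiply(dv, dv, out=dv)
        du += dv
        gmin[sl] = du.min(axis=1)

    gamma = np.full(dm.shape, np.nan)
    gamma[mask] = np.sqrt(gmin)
    n_analyzed = int(mask.sum())
    n_passing = int(np.sum(gamma[mask] <= 1.0 + _PASS_EPS))
    return GammaResult(
        gamma=gamma,
        mask=mask,
        params=params,
        n_analyzed=n_analyzed,
        n_passing=n_passing,
        n_excluded_invalid_calc=n_excl,
    )


# ---------------------------------------------------------------------------
# Summaries, profiles, contours


def pass_rate_summary(results) -> dict:
    """Mean / max / min / sample SD (n-1 denominator) of pass rates (%).

    Accepts GammaResult objects or plain percentages.  With a single
    value the SD is reported as 0.0 and flagged.
    """
    rates = [r.pass_rate if isinstance(r, GammaResult) else float(r)
             for r in results]
    if not rates:
        raise ValueError("need at least one pass rate")
    arr = np.asarray(rates, dtype=float)
    single = arr.size == 1
    return {
        "mean": float(arr.mean()),
        "max": float(arr.max()),
        "min": float(arr.min()),
        "sd": 0.0 if single else float(arr.std(ddof=1)),
        "n": int(arr.size),
        "sd_undefined": bool(single),
    }


def radial_profiles(
    measured: PlanarDoseMap,
    calculated: PlanarDoseMap,
    angle_step: float = 12.0,
    origin: tuple[float, float] | None = None,
) -> list[dict]:
    """Paired radial dose profiles at fixed angular intervals.

    Rays start at the film center (or ``origin`` in (u, v) cm) and run
    to the film edge, sampled bilinearly at half-pixel spacing; each
    distribution is normalised to its own plane maximum.  Returns one
    record per angle with keys angle_deg, radius_cm, measured, calculated.
    """
    if angle_step <= 0 or abs(360.0 / angle_step - round(360.0 / angle_step)) > 1e-9:
        raise ValueError("angle_step must divide 360")
    nv, nu = measured.values.shape
    # rays are bounded by the pixel-center extent, where bilinear sampling
    # is defined
    u0, v0 = measured.origin_uv
    extent_u = (nu - 1) * measured.pitch[0]
    extent_v = (nv - 1) * measured.pitch[1]
    if origin is None:
        origin = (u0 + extent_u / 2.0, v0 + extent_v / 2.0)
    ds = min(measured.pitch) / 2.0
    m_max = measured.max_dose()
    c_max = calculated.max_dose()
    out = []
    for k in range(int(round(360.0 / angle_step))):
        ang = math.radians(k * angle_step)
        cu, sv = math.cos(ang), math.sin(ang)
        # distance from origin to the film rectangle edge along the ray
        tmax = np.inf
        for comp, lo, hi, o in ((cu, u0, u0 + extent_u, origin[0]),
                                (sv, v0, v0 + extent_v, origin[1])):
            if comp > 1e-15:
                tmax = min(tmax, (hi - o) / comp)
            elif comp < -1e-15:
                tmax = min(tmax, (lo - o) / comp)
        radii = np.arange(0.0, tmax + ds * 1e-9, ds)
        uq = origin[0] + radii * cu
        vq = origin[1] + radii * sv
        out.append(
            {
                "angle_deg": k * angle_step,
                "radius_cm": radii,
                "measured": sample_map(measured, uq, vq) / m_max,
                "calculated": sample_map(calculated, uq, vq) / c_max,
            }
        )
    return out


def isodose_contours(dmap: PlanarDoseMap, step: float = 0.10) -> list[dict]:
    """Marching-squares isodose contours at fractions step, 2*step, ... 90%.

    Levels are fractions of the plane maximum; each returned record has
    ``level`` (the fraction) and ``vertices`` as an (N, 2) array of
    (u, v) cm.
    """
    if not 0 < step < 1:
        raise ValueError("step must be a fraction in (0, 1)")
    vmax = dmap.max_dose()
    values = np.nan_to_num(dmap.values, nan=0.0)
    out = []
    n_levels = int(math.floor(0.9 / step + 1e-9))
    for k in range(1, n_levels + 1):
        frac = k * step
        for poly in measure.find_contours(values, frac * vmax):
            uv = np.column_stack(
                [
                    dmap.origin_uv[0] + poly[:, 1] * dmap.pitch[0],
                    dmap.origin_uv[1] + poly[:, 0] * dmap.pitch[1],
                ]
            )
            out.append({"level": frac, "vertices": uv})
    return out
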