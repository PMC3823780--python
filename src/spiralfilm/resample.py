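"""Resample a 3D dose grid onto the spiral film surface or orthogonal planes.

The calculated 3D distribution is evaluated by trilinear interpolation
directly on the film raster (pixel centers of the flat film unrolled in
(u, v)), so no second regridding is needed when comparing with a scanned
film.  Central transverse / coronal / sagittal planes are extracted the
same way for plane-by-plane pass-rate comparisons.
"""

from __future__ import annotations

import logging

import numpy as np

from .dose_io import DoseGrid, PlanarDoseMap, trilinear
from .geometry import SpiralGeometry, film_to_phantom

__all__ = [
    "FILM_SCAN_PITCH_CM",
    "resample_spiral",
    "extract_orthogonal_plane",
    "point_dose",
]

log = logging.getLogger(__name__)

#: default raster pitch: the 72-dpi film-scan pixel pitch (2.54/72 cm)
FILM_SCAN_PITCH_CM = 2.54 / 72.0


def _raster(length: float, pitch: float) -> np.ndarray:
    """Pixel-center coordinates covering [0, length] at the given pitch."""
    n = int(np.floor(length / pitch + 1e-9))
    return (np.arange(n) + 0.5) * pitch


def resample_spiral(
    grid: DoseGrid,
    geom: SpiralGeometry,
    pitch: float = FILM_SCAN_PITCH_CM,
) -> PlanarDoseMap:
    """Calculated dose on the spiral film surface, on the film raster.

    Each film pixel center (u, v) is mapped to its 3D phantom point and
    the grid interpolated there; pixels falling outside the grid are
    NaN (invalid) and counted in the log.  Raises if more than half the
    pixels are outside (geometry/grid mismatch).
    """
    if pitch <= 0:
        raise ValueError("pitch must be positive")
    u = _raster(geom.film_arc_length, pitch)
    v = _raster(geom.film_width, pitch)
    uu, vv = np.meshgrid(u, v)  # rows = v
    pts = film_to_phantom(uu.ravel(), vv.ravel(), geom)
    doses = trilinear(grid, pts).reshape(vv.shape)
    n_invalid = int(np.isnan(doses).sum())
    if n_invalid:
        log.info("resample_spiral: %d/%d pixels outside grid", n_invalid, doses.size)
    if n_invalid > 0.5 * doses.size:
        raise ValueError(
            f"{n_invalid}/{doses.size} spiral pixels fall outside the dose grid; "
            "geometry and grid do not match"
        )
    return PlanarDoseMap(
        values=doses,
        pitch=(pitch, pitch),
        origin_uv=(u[0], v[0]),
        plane_label="spiral",
    )


_PLANE_AXES = {
    # plane -> (in-plane axis for u, in-plane axis for v, normal axis)
    "transverse": (0, 1, 2),  # x, y at fixed z
    "coronal": (0, 2, 1),  # x, z at fixed y
    "sagittal": (1, 2, 0),  # y, z at fixed x
}


def extract_orthogonal_plane(
    grid: DoseGrid,
    plane: str,
    offset: float = 0.0,
    pitch: float = FILM_SCAN_PITCH_CM,
    center=(0.0, 0.0, 0.0),
) -> PlanarDoseMap:
    """Dose on a transverse/coronal/sagittal plane through the isocenter.

    ``offset`` (cm) displaces the plane along its normal from the
    central position; the raster spans the grid's extent in-plane.
    """
    if plane not in _PLANE_AXES:
        raise ValueError(f"unknown plane {plane!r}")
    if pitch <= 0:
        raise ValueError("pitch must be positive")
    au, av, an = _PLANE_AXES[plane]
    lo = grid.origin
    hi = grid.origin + (np.asarray(grid.shape) - 1) * grid.spacing
    u = np.arange(lo[au], hi[au] + pitch * 1e-9, pitch)
    v = np.arange(lo[av], hi[av] + pitch * 1e-9, pitch)
    uu, vv = np.meshgrid(u, v)
    pts = np.empty(uu.shape + (3,))
    pts[..., au] = uu
    pts[..., av] = vv
    pts[..., an] = center[an] + offset
    doses = trilinear(grid, pts.reshape(-1, 3)).reshape(uu.shape)
    if np.all(np.isnan(doses)):
        raise ValueError(f"{plane} plane at offset {offset} does not intersect grid")
    return PlanarDoseMap(
        values=doses,
        pitch=(pitch, pitch),
        origin_uv=(float(u[0]), float(v[0])),
        plane_label=plane,
    )


def point_dose(grid: DoseGrid, p) -> float:
    """Trilinear dose (cGy) at a single phantom point, e.g. the chamber point."""
    val = trilinear(grid, np.asarray(p, dtype=float))
    if val is None:
        raise ValueError(f"point {p} lies outside the dose grid")
    return val
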