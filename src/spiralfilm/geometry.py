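"""Archimedean-spiral film surface of the spiral water phantom.

A radiochromic film (13.0 cm x 25.4 cm) is held on a developable spiral
surface inside a cylindrical water phantom.  The spiral trajectory in the
transverse plane is ``r = a * theta`` with a constant radial pitch of
``2*pi*a`` between successive turns; the film's long edge runs along the
arc, its short edge along the cylinder axis.  This module provides the
exact analytic bijection between flat-film coordinates ``(u, v)`` --
``u`` measured along the arc from the inner film edge, ``v`` along the
axis from one film edge -- and 3D phantom coordinates ``(x, y, z)``
centred on the isocenter.

The default constants reproduce the published phantom: ``a = 0.5129``
cm/rad, minimum polar angle ``pi/3`` (limited by the film's mechanical
flexibility), film arc length 25.4 cm and width 13.0 cm.  The maximum
polar angle is never set directly; it is derived so the spiral arc
between ``theta_min`` and ``theta_max`` equals the film arc length
(about 9.899 rad, ~1.6 turns, for the defaults).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "SpiralGeometry",
    "radius_at",
    "arc_length",
    "theta_from_arc_length",
    "solve_theta_max",
    "film_to_phantom",
    "phantom_to_film",
]

_ARC_TOL_CM = 1e-12


def _arc_length_scalar(a: float, theta: float) -> float:
    # closed form of integral_0^theta a*sqrt(1+t^2) dt for r = a*theta
    return 0.5 * a * (theta * math.sqrt(1.0 + theta * theta) + math.asinh(theta))


@dataclass(frozen=True)
class SpiralGeometry:
    """Spiral film surface: constants, angular range and phantom frame.

    Parameters
    ----------
    a : float
        Spiral constant in cm/radian (``r = a * theta``).
    theta_min : float
        Polar angle of the inner film edge, radians, >= 0.
    film_width : float
        Axial film extent (v-direction), cm.
    film_arc_length : float
        Film extent along the arc (u-direction), cm.  ``theta_max`` is
        always derived from this value.
    handedness : str
        ``"counterclockwise"`` (theta increases toward +y seen from +z)
        or ``"clockwise"``.
    axis_origin : tuple
        Isocenter of the phantom frame, cm.
    """

    a: float = 0.5129
    theta_min: float = math.pi / 3.0
    film_width: float = 13.0
    film_arc_length: float = 25.4
    handedness: str = "counterclockwise"
    axis_origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    theta_max: float = field(init=False)

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"spiral constant a must be > 0, got {self.a}")
        if self.theta_min < 0:
            raise ValueError(f"theta_min must be >= 0, got {self.theta_min}")
        if self.film_width <= 0:
            raise ValueError(f"film_width must be > 0, got {self.film_width}")
        if self.film_arc_length <= 0:
            raise ValueError(
                f"film_arc_length must be > 0, got {self.film_arc_length}"
            )
        if self.handedness not in ("counterclockwise", "clockwise"):
            raise ValueError(f"unknown handedness {self.handedness!r}")
        object.__setattr__(self, "theta_max", solve_theta_max(self))

    @property
    def s_min(self) -> float:
        """Arc length from theta = 0 to the inner film edge, cm."""
        return _arc_length_scalar(self.a, self.theta_min)

    @property
    def r_max(self) -> float:
        """Outer radius of the spiral surface, cm."""
        return self.a * self.theta_max


def radius_at(theta, geom: SpiralGeometry):
    """Radial distance ``r = a * theta`` of the spiral at polar angle theta (cm)."""
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0):
        raise ValueError("theta must be >= 0")
    out = geom.a * theta
    return float(out) if out.ndim == 0 else out


def arc_length(theta, geom: SpiralGeometry):
    """Arc length of the spiral from theta = 0 to ``theta``, cm.

    Uses the closed form s(t) = (a/2) [ t sqrt(1+t^2) + asinh(t) ],
    strictly increasing with s(0) = 0.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0):
        raise ValueError("theta must be >= 0")
    out = 0.5 * geom.a * (theta * np.sqrt(1.0 + theta * theta) + np.arcsinh(theta))
    return float(out) if out.ndim == 0 else out


def theta_from_arc_length(s, geom: SpiralGeometry):
    """Invert the arc-length map: the theta with ``arc_length(theta) = s``.

    ``s`` is measured from theta = 0 and must lie in
    ``[0, arc_length(theta_max)]``.  Solved by safeguarded Newton
    iteration (the derivative a*sqrt(1+theta^2) is known exactly);
    accurate to well below 1e-9 cm in arc length.
    """
    s_arr = np.asarray(s, dtype=float)
    s_max = arc_length(geom.theta_max, geom)
    if np.any(s_arr < -_ARC_TOL_CM) or np.any(s_arr > s_max * (1 + 1e-12) + 1e-9):
        raise ValueError(
            f"arc length out of range [0, {s_max:.6f}] cm"
        )
    s_c = np.clip(s_arr, 0.0, s_max)
    # initial guess from the quadratic large-theta behaviour s ~ a theta^2 / 2
    theta = np.sqrt(2.0 * s_c / geom.a)
    lo = np.zeros_like(theta)
    hi = np.full_like(theta, geom.theta_max * (1 + 1e-9) + 1e-9)
    for _ in range(60):
        f = 0.5 * geom.a * (theta * np.sqrt(1 + theta**2) + np.arcsinh(theta)) - s_c
        lo = np.where(f < 0, theta, lo)
        hi = np.where(f > 0, theta, hi)
        step = f / (geom.a * np.sqrt(1.0 + theta * theta))
        nxt = theta - step
        # bisect whenever Newton leaves the bracket
        bad = (nxt < lo) | (nxt > hi)
        nxt = np.where(bad, 0.5 * (lo + hi), nxt)
        if np.all(np.abs(nxt - theta) < 1e-15 * (1 + np.abs(theta))):
            theta = nxt
            break
        theta = nxt
    return float(theta) if theta.ndim == 0 else theta


def solve_theta_max(geom: SpiralGeometry) -> float:
    """theta at which the arc from theta_min spans the film arc length.

    Root of ``arc_length(theta) - arc_length(theta_min) - film_arc_length``,
    solved with Brent's method; satisfies the constraint to < 1e-9 cm.
    """
    target = _arc_length_scalar(geom.a, geom.theta_min) + geom.film_arc_length
    f = lambda t: _arc_length_scalar(geom.a, t) - target  # noqa: E731
    hi = max(geom.theta_min + 1.0, math.sqrt(2.0 * target / geom.a) + 2.0)
    while f(hi) < 0:
        hi *= 2.0
    return brentq(f, geom.theta_min, hi, xtol=1e-13, rtol=8.9e-16)


def _theta_of_u(u, geom: SpiralGeometry):
    return theta_from_arc_length(geom.s_min + np.asarray(u, dtype=float), geom)


def film_to_phantom(u, v, geom: SpiralGeometry):
    """Map flat-film coordinates (u, v) in cm to a 3D phantom point, cm.

    u runs along the arc from the theta_min edge, v along the axis from
    one film edge; the film is axially centred on the isocenter plane,
    so z = v - film_width/2.  Accepts scalars or broadcastable arrays;
    returns an array of shape (..., 3).  The map is injective.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any(u < -1e-12) or np.any(u > geom.film_arc_length + 1e-12):
        raise ValueError("u outside [0, film_arc_length]")
    if np.any(v < -1e-12) or np.any(v > geom.film_width + 1e-12):
        raise ValueError("v outside [0, film_width]")
    theta = _theta_of_u(u, geom)
    r = geom.a * theta
    sign = 1.0 if geom.handedness == "counterclockwise" else -1.0
    u_b, v_b = np.broadcast_arrays(u, v)
    theta = np.broadcast_to(theta, u_b.shape)
    r = np.broadcast_to(r, u_b.shape)
    p = np.stack(
        [
            r * np.cos(theta),
            sign * r * np.sin(theta),
            v_b - geom.film_width / 2.0,
        ],
        axis=-1,
    )
    return p + np.asarray(geom.axis_origin, dtype=float)


def phantom_to_film(p, geom: SpiralGeometry, tol: float = 0.05):
    """Inverse map: 3D phantom point -> (u, v), or None if off-surface.

    The winding is disambiguated by picking the theta in
    ``[theta_min, theta_max]`` that matches the point's polar angle
    modulo 2*pi and minimises ``|r(theta) - |p_xy||``; a point radially
    farther than ``tol`` (cm) from every candidate turn, or outside the
    film's axial extent, is reported as off-surface (None).  A point
    equidistant from two turns resolves to the smaller theta.
    """
    p = np.asarray(p, dtype=float) - np.asarray(geom.axis_origin, dtype=float)
    x, y, z = p
    sign = 1.0 if geom.handedness == "counterclockwise" else -1.0
    rho = math.hypot(x, y)
    if rho == 0.0:
        return None  # cylinder axis never lies on the spiral
    phi = math.atan2(sign * y, x) % (2.0 * math.pi)
    # candidate windings: theta = phi + 2*pi*k inside [theta_min, theta_max]
    k_lo = math.floor((geom.theta_min - phi) / (2.0 * math.pi))
    k_hi = math.ceil((geom.theta_max - phi) / (2.0 * math.pi))
    best = None
    for k in range(k_lo, k_hi + 1):
        theta = phi + 2.0 * math.pi * k
        if theta < geom.theta_min - 1e-12 or theta > geom.theta_max + 1e-12:
            continue
        resid = abs(geom.a * theta - rho)
        if resid <= tol and (best is None or resid < best[1] - 1e-15):
            best = (theta, resid)
    if best is None:
        return None
    theta = min(max(best[0], geom.theta_min), geom.theta_max)
    v = z + geom.film_width / 2.0
    if v < -tol or v > geom.film_width + tol:
        return None
    u = _arc_length_scalar(geom.a, theta) - geom.s_min
    u = min(max(u, 0.0), geom.film_arc_length)
    v = min(max(v, 0.0), geom.film_width)
    return (u, v)
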