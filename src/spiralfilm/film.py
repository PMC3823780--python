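"""Radiochromic film handling: scans, netOD, calibration, dose conversion.

The scanned film is a 48-bit RGB TIFF; only the red channel carries the
dose signal for EBT2-type film in the 0-320 cGy range.  The film's
dose-responding quantity is the net optical density

    netOD = log10(I_unexposed / I_exposed)

referenced to the 0-cGy calibration piece, and dose is recovered through
the fitted response

    D(netOD) = b * netOD + c * netOD**n,   b, c >= 0,  1.5 <= n <= 4,

which is zero at zero exposure and monotone increasing by construction.
A single curve per run is assumed (one film batch, one set of scanning
conditions).  The 24-h post-irradiation darkening wait is metadata only
(scan_delay_hours); it has no computational effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import map_coordinates
from scipy.optimize import curve_fit

from .dose_io import PlanarDoseMap

__all__ = [
    "FilmScan",
    "CalibrationCurve",
    "read_scan",
    "write_scan",
    "net_od",
    "fit_calibration",
    "read_calibration_table",
    "od_to_dose",
    "register_film",
]

log = logging.getLogger(__name__)


@dataclass
class FilmScan:
    """Red-channel data of a flatbed film scan."""

    red_channel: np.ndarray  # 2D uint16, rows = v
    dpi: float
    bit_depth: int = 16
    scan_mode_label: str = "landscape 48-bit RGB"
    scan_delay_hours: float = 24.0

    def __post_init__(self) -> None:
        self.red_channel = np.asarray(self.red_channel)
        if self.red_channel.ndim != 2:
            raise ValueError("red channel must be 2D")
        if self.dpi <= 0:
            raise ValueError("dpi must be positive")

    @property
    def pitch_cm(self) -> float:
        """Pixel pitch in cm (2.54/dpi)."""
        return 2.54 / self.dpi


@dataclass
class CalibrationCurve:
    """Fitted netOD -> dose response with its control points."""

    control_points: list[tuple[float, float]]  # (dose cGy, netOD)
    b: float
    c: float
    n: float
    fit_residual: float  # RMS dose error at control points, cGy
    valid_range: tuple[float, float] = (0.0, 1.0)
    unexposed_value: float = field(default=40000.0)

    def dose(self, net_od):
        """Evaluate D = b*netOD + c*netOD**n (cGy); netOD clipped at 0."""
        od = np.clip(np.asarray(net_od, dtype=float), 0.0, None)
        out = self.b * od + self.c * np.power(od, self.n)
        return float(out) if out.ndim == 0 else out

    def dose_derivative(self, net_od):
        od = np.clip(np.asarray(net_od, dtype=float), 1e-300, None)
        out = self.b + self.c * self.n * np.power(od, self.n - 1.0)
        return float(out) if out.ndim == 0 else out

    def net_od_from_dose(self, dose, tol: float = 1e-12):
        """Invert the monotone response numerically (Newton with bisection seed)."""
        d = np.asarray(dose, dtype=float)
        if np.any(d < 0):
            raise ValueError("dose must be non-negative")
        od_hi = max(self.valid_range[1], 1.0)
        # monotone seed from a dense table, then Newton refinement
        grid = np.linspace(0.0, od_hi, 4097)
        od = np.interp(d, self.dose(grid), grid)
        for _ in range(8):
            f = self.dose(od) - d
            od = np.clip(od - f / self.dose_derivative(od), 0.0, od_hi)
            if np.all(np.abs(f) <= tol * (1.0 + d)):
                break
        return float(od) if od.ndim == 0 else od

    def to_dict(self) -> dict:
        return {
            "model": "D = b*netOD + c*netOD^n",
            "b": self.b,
            "c": self.c,
            "n": self.n,
            "fit_residual_cGy": self.fit_residual,
            "valid_range": list(self.valid_range),
            "unexposed_value": self.unexposed_value,
            "control_points": [list(p) for p in self.control_points],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        return cls(
            control_points=[tuple(p) for p in d["control_points"]],
            b=d["b"],
            c=d["c"],
            n=d["n"],
            fit_residual=d["fit_residual_cGy"],
            valid_range=tuple(d["valid_range"]),
            unexposed_value=d.get("unexposed_value", 40000.0),
        )


# ---------------------------------------------------------------------------
# Scan I/O


def read_scan(path, dpi: float | None = None) -> FilmScan:
    """Read a 16-bit-per-channel RGB TIFF film scan; extract the red channel.

    The dpi is taken from the TIFF resolution tags unless supplied.  An
    8-bit file is accepted with a warning and upscaled to 16 bit
    (value * 257); a single-channel file is rejected.
    """
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        if dpi is None:
            res = page.tags.get("XResolution")
            unit = page.tags.get("ResolutionUnit")
            # unit NONE (1) means the resolution tag carries no physical scale
            if res is not None and unit is not None and unit.value in (2, 3):
                num, den = res.value
                dpi = num / den
                if unit.value == 3:  # pixels per centimetre
                    dpi *= 2.54
    if dpi is None or dpi <= 0:
        raise ValueError("scan dpi not present in file and not supplied")
    if data.ndim != 3 or data.shape[-1] < 3:
        raise ValueError(
            f"expected an RGB scan with >= 3 channels, got shape {data.shape}"
        )
    red = data[..., 0]
    if red.dtype == np.uint8:
        log.warning("8-bit scan %s upscaled to 16 bit", path)
        red = red.astype(np.uint16) * 257
    return FilmScan(red_channel=red.astype(np.uint16), dpi=float(dpi))


def write_scan(scan: FilmScan, path) -> None:
    """Write a FilmScan as a 16-bit RGB TIFF with dpi metadata.

    Green and blue are filled with the red channel (the synthetic scans
    carry no independent colour information).
    """
    rgb = np.repeat(scan.red_channel[..., None], 3, axis=-1).astype(np.uint16)
    tifffile.imwrite(
        path,
        rgb,
        photometric="rgb",
        resolution=(scan.dpi, scan.dpi),
        resolutionunit="INCH",
    )


# ---------------------------------------------------------------------------
# netOD


def net_od(exposed: FilmScan, unexposed) -> np.ndarray:
    """netOD map log10(I0/I), clipped below at 0.

    ``unexposed`` may be a FilmScan on the same raster or a scalar
    reference value (mean red value of the 0-cGy piece).  Zero
    intensities are replaced by 0.5 LSB with a logged warning.
    """
    i = exposed.red_channel.astype(float)
    if isinstance(unexposed, FilmScan):
        if unexposed.red_channel.shape != i.shape:
            raise ValueError("exposed and unexposed scans are on different rasters")
        i0 = unexposed.red_channel.astype(float)
    else:
        i0 = float(unexposed)
    n_zero = int(np.sum(i == 0))
    if n_zero:
        log.warning("net_od: %d zero pixels mapped to 0.5 LSB", n_zero)
        i = np.where(i == 0, 0.5, i)
    i0 = np.where(i0 == 0, 0.5, i0)
    return np.clip(np.log10(i0 / i), 0.0, None)


# ---------------------------------------------------------------------------
# Calibration


def _response(od, b, c, n):
    return b * od + c * np.power(od, n)


def fit_calibration(points, unexposed_value: float = 40000.0) -> CalibrationCurve:
    """Least-squares fit of D = b*netOD + c*netOD**n to control points.

    ``points`` is a sequence of (dose cGy, netOD) including dose 0; the
    fit minimises squared dose error subject to b, c >= 0 and
    n in [1.5, 4], which keeps the curve monotone with D(0) = 0.
    """
    pts = sorted((float(d), float(od)) for d, od in points)
    if len(pts) < 4:
        raise ValueError("need at least 4 calibration points")
    if pts[0][0] != 0.0:
        raise ValueError("calibration series must include dose 0")
    doses = np.array([p[0] for p in pts])
    ods = np.array([p[1] for p in pts])
    if np.any(np.diff(doses) <= 0):
        raise ValueError("control point doses must be strictly increasing")
    bad = [
        f"({doses[k]:g} cGy, {ods[k]:g}) vs ({doses[k + 1]:g} cGy, {ods[k + 1]:g})"
        for k in range(len(pts) - 1)
        if ods[k + 1] <= ods[k]
    ]
    if bad:
        raise ValueError(
            "netOD must increase with dose; offending pairs: " + "; ".join(bad)
        )
    # fit on the nonzero points (the model passes through the origin exactly)
    mask = doses > 0
    slope0 = doses[mask][0] / max(ods[mask][0], 1e-9)
    p0 = (slope0, slope0, 2.5)
    popt, _ = curve_fit(
        _response,
        ods[mask],
        doses[mask],
        p0=p0,
        bounds=([0.0, 0.0, 1.5], [np.inf, np.inf, 4.0]),
        maxfev=20000,
    )
    b, c, n = (float(v) for v in popt)
    resid = float(np.sqrt(np.mean((_response(ods, b, c, n) - doses) ** 2)))
    return CalibrationCurve(
        control_points=pts,
        b=b,
        c=c,
        n=n,
        fit_residual=resid,
        valid_range=(0.0, float(ods.max())),
        unexposed_value=unexposed_value,
    )


def read_calibration_table(path) -> list[tuple[float, float]]:
    """Read a calibration CSV with columns ``dose_cGy,netOD`` or
    ``dose_cGy,red_value``.

    Raw red values are converted to netOD against the 0-cGy row.
    """
    df = pd.read_csv(path)
    if "dose_cGy" not in df.columns:
        raise ValueError("calibration table must have a dose_cGy column")
    if "netOD" in df.columns:
        return list(zip(df["dose_cGy"].astype(float), df["netOD"].astype(float)))
    if "red_value" in df.columns:
        doses = df["dose_cGy"].astype(float).to_numpy()
        red = df["red_value"].astype(float).to_numpy()
        zero = red[doses == 0]
        if zero.size == 0:
            raise ValueError("red_value table must include a dose-0 row")
        ods = np.clip(np.log10(zero[0] / red), 0.0, None)
        return list(zip(doses, ods))
    raise ValueError("calibration table needs a netOD or red_value column")


def od_to_dose(
    od_map: np.ndarray,
    curve: CalibrationCurve,
    pitch_cm: float,
    plane_label: str = "film",
) -> PlanarDoseMap:
    """Convert a netOD map to a measured dose map via the fitted curve.

    netOD above the calibrated range is clipped to the range maximum and
    the clip count logged; output pitch is the scan pitch.
    """
    od = np.asarray(od_map, dtype=float)
    hi = curve.valid_range[1]
    n_clip = int(np.sum(od > hi))
    if n_clip:
        log.warning("od_to_dose: %d pixels above calibrated netOD range clipped",
                    n_clip)
    od = np.clip(od, 0.0, hi)
    return PlanarDoseMap(
        values=curve.dose(od),
        pitch=(pitch_cm, pitch_cm),
        origin_uv=(pitch_cm / 2.0, pitch_cm / 2.0),
        plane_label=plane_label,
    )


# ---------------------------------------------------------------------------
# Registration


def register_film(
    measured: PlanarDoseMap,
    flips: tuple[bool, bool] = (False, False),
    offset: tuple[float, float] = (0.0, 0.0),
) -> PlanarDoseMap:
    """Apply axis flips and a rigid in-plane translation to a measured map.

    No rotation and no scaling: the spiral grooves fix the film's
    rotation physically, so registration has only mirror/offset freedom.
    The translation is in cm in (u, v); resampling is bilinear and
    pixels shifted in from outside the map become NaN (invalid).
    """
    values = measured.values
    if flips[0]:
        values = values[:, ::-1]
    if flips[1]:
        values = values[::-1, :]
    du, dv = offset
    if du == 0.0 and dv == 0.0:
        shifted = values.copy()
    else:
        nv, nu = values.shape
        jj, ii = np.meshgrid(np.arange(nu), np.arange(nv))
        # content moves by +offset: sample the source at x - offset
        coords = np.stack(
            [ii - dv / measured.pitch[1], jj - du / measured.pitch[0]]
        )
        filled = np.nan_to_num(values, nan=0.0)
        shifted = map_coordinates(filled, coords, order=1, cval=np.nan,
                                  mode="constant")
        invalid = map_coordinates(
            np.isnan(values).astype(float), coords, order=1, cval=1.0,
            mode="constant",
        )
        shifted = np.where(invalid > 1e-9, np.nan, shifted)
    return PlanarDoseMap(
        values=shifted,
        pitch=measured.pitch,
        origin_uv=measured.origin_uv,
        plane_label=measured.plane_label,
    )
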