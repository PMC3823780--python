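"""Dose containers and I/O: DICOM RT Dose grids and planar dose maps.

All lengths are centimetres and all doses centigray internally; DICOM
millimetres and gray are converted at the boundary.  Voxel coordinates
refer to voxel *centers*, and interpolation is only defined inside the
center-to-center bounding box -- there is no extrapolation.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

__all__ = [
    "DoseGrid",
    "PlanarDoseMap",
    "DoseFormatError",
    "read_rtdose",
    "write_rtdose",
    "trilinear",
    "write_planar_map",
    "read_planar_map",
]

_RTDOSE_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.2"


class DoseFormatError(ValueError):
    """Raised for malformed or unsupported dose files."""


@dataclass
class DoseGrid:
    """3D calculated dose distribution on a regular grid.

    ``values[ix, iy, iz]`` is the dose in cGy at
    ``origin + orientation @ (ix*dx, iy*dy, iz*dz)``; ``origin`` is the
    center of voxel (0, 0, 0) in cm.
    """

    values: np.ndarray
    origin: np.ndarray
    spacing: np.ndarray
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))
    frame_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.orientation = np.asarray(self.orientation, dtype=float).reshape(3, 3)
        if self.values.ndim != 3:
            raise ValueError("dose values must be a 3D array")
        if np.any(self.spacing <= 0):
            raise ValueError("grid spacing must be positive")
        if not np.allclose(
            self.orientation @ self.orientation.T, np.eye(3), atol=1e-6
        ):
            raise ValueError("orientation must be orthonormal")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("dose values must be finite and non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def voxel_center(self, idx) -> np.ndarray:
        """Phantom-frame position (cm) of voxel index (ix, iy, iz)."""
        ijk = np.asarray(idx, dtype=float) * self.spacing
        return self.origin + self.orientation @ ijk


@dataclass
class PlanarDoseMap:
    """2D dose map on a regular (u, v) raster.

    ``values[iv, iu]`` (image convention: rows are v) is the dose in cGy
    at ``(origin_uv[0] + iu*du, origin_uv[1] + iv*dv)``; origin_uv is
    the center of pixel (0, 0).  NaN marks invalid pixels (outside the
    source grid); they are excluded from every downstream analysis.
    """

    values: np.ndarray
    pitch: tuple[float, float]
    origin_uv: tuple[float, float] = (0.0, 0.0)
    plane_label: str = "film"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("planar map values must be 2D")
        if self.pitch[0] <= 0 or self.pitch[1] <= 0:
            raise ValueError("pixel pitch must be positive")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and np.any(finite < 0):
            raise ValueError("dose values must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def u_coords(self) -> np.ndarray:
        return self.origin_uv[0] + np.arange(self.values.shape[1]) * self.pitch[0]

    def v_coords(self) -> np.ndarray:
        return self.origin_uv[1] + np.arange(self.values.shape[0]) * self.pitch[1]

    def max_dose(self) -> float:
        return float(np.nanmax(self.values))


# ---------------------------------------------------------------------------
# DICOM RT Dose


def read_rtdose(path) -> DoseGrid:
    """Read a DICOM RT Dose file into a :class:`DoseGrid` (cm / cGy).

    Stored integers are multiplied by DoseGridScaling; the pixel array's
    (frame, row, column) axes map to patient (z, y, x), so the returned
    values are transposed to ``[ix, iy, iz]``.  Raises
    :class:`DoseFormatError` on a missing scaling attribute, non-uniform
    frame offsets, or unsupported dose units.
    """
    ds = pydicom.dcmread(path)
    if "DoseGridScaling" not in ds:
        raise DoseFormatError("RT Dose is missing DoseGridScaling")
    units = str(getattr(ds, "DoseUnits", "GY")).upper()
    if units == "GY":
        to_cgy = 100.0
    elif units == "CGY":
        to_cgy = 1.0
    else:
        raise DoseFormatError(f"unsupported DoseUnits {units!r}")
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    if offsets.size < 2:
        raise DoseFormatError("GridFrameOffsetVector must list >= 2 frames")
    dz_all = np.diff(offsets)
    if not np.allclose(dz_all, dz_all[0], atol=1e-6):
        raise DoseFormatError("non-uniform GridFrameOffsetVector")
    dz_mm = float(dz_all[0])
    if dz_mm <= 0:
        raise DoseFormatError("GridFrameOffsetVector must be increasing")
    row_mm, col_mm = (float(v) for v in ds.PixelSpacing)
    ipp_mm = np.asarray(ds.ImagePositionPatient, dtype=float)
    iop = np.asarray(
        getattr(ds, "ImageOrientationPatient", [1, 0, 0, 0, 1, 0]), dtype=float
    )
    row_dir, col_dir = iop[3:6], iop[0:3]
    normal = np.cross(col_dir, row_dir)
    orientation = np.column_stack([col_dir, row_dir, normal])
    stored = ds.pixel_array.astype(np.float64)  # (frames, rows, cols)
    values = stored.transpose(2, 1, 0) * float(ds.DoseGridScaling) * to_cgy
    return DoseGrid(
        values=values,
        origin=ipp_mm / 10.0,
        spacing=np.array([col_mm, row_mm, dz_mm]) / 10.0,
        orientation=orientation,
        frame_label=str(getattr(ds, "FrameOfReferenceUID", "")),
    )


def write_rtdose(grid: DoseGrid, path) -> None:
    """Write a minimal standard-conforming RT Dose file (16-bit, GY units).

    DoseGridScaling is chosen as max_dose / (2**16 - 1) so the largest
    stored integer fills the 16-bit range (quantisation < 0.002% of the
    maximum dose).
    """
    if grid.values.size == 0:
        raise ValueError("cannot write an empty dose grid")
    max_cgy = float(grid.values.max())
    scaling_gy = (max_cgy / 100.0) / 65535.0 if max_cgy > 0 else 1.0
    stored = np.round(grid.values / 100.0 / scaling_gy).astype(np.uint16)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = _RTDOSE_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = _RTDOSE_SOP_CLASS
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.SeriesInstanceUID = generate_uid()
    ds.StudyInstanceUID = generate_uid()
    ds.FrameOfReferenceUID = grid.frame_label or generate_uid()
    ds.PatientName = "PHANTOM^SPIRAL"
    ds.PatientID = "SPIRAL-QA"
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.DoseGridScaling = scaling_gy
    nx, ny, nz = grid.shape
    ds.Rows = ny
    ds.Columns = nx
    ds.NumberOfFrames = nz
    ds.PixelSpacing = [grid.spacing[1] * 10.0, grid.spacing[0] * 10.0]
    ds.ImagePositionPatient = [float(c) * 10.0 for c in grid.origin]
    ds.ImageOrientationPatient = [
        *(float(c) for c in grid.orientation[:, 0]),
        *(float(c) for c in grid.orientation[:, 1]),
    ]
    dz_mm = grid.spacing[2] * 10.0
    ds.GridFrameOffsetVector = [float(k * dz_mm) for k in range(nz)]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelData = np.ascontiguousarray(stored.transpose(2, 1, 0)).tobytes()
    ds.save_as(path, enforce_file_format=True)


# ---------------------------------------------------------------------------
# Interpolation


def trilinear(grid: DoseGrid, p, outside=None):
    """Trilinear interpolation of the dose grid at point(s) p (cm).

    Standard interpolation among the 8 surrounding voxel centers; a
    point outside the voxel-center bounding box yields ``outside``
    (default None for a scalar query, NaN in array queries).  General
    orthonormal orientations are handled by rotating the query point
    into the grid frame.
    """
    p = np.asarray(p, dtype=float)
    scalar = p.ndim == 1
    pts = np.atleast_2d(p)
    local = (pts - grid.origin) @ grid.orientation  # == R.T @ (p - origin)
    f = local / grid.spacing
    shape = np.asarray(grid.shape)
    inside = np.all((f >= -1e-12) & (f <= shape - 1 + 1e-12), axis=1)
    f = np.clip(f, 0.0, shape - 1)
    i0 = np.minimum(f.astype(int), shape - 2)
    i0 = np.maximum(i0, 0)
    t = f - i0
    v = grid.values
    ix, iy, iz = i0[:, 0], i0[:, 1], i0[:, 2]
    tx, ty, tz = t[:, 0], t[:, 1], t[:, 2]

    def corner(dx, dy, dz):
        return v[
            np.minimum(ix + dx, shape[0] - 1),
            np.minimum(iy + dy, shape[1] - 1),
            np.minimum(iz + dz, shape[2] - 1),
        ]

    c00 = corner(0, 0, 0) * (1 - tx) + corner(1, 0, 0) * tx
    c10 = corner(0, 1, 0) * (1 - tx) + corner(1, 1, 0) * tx
    c01 = corner(0, 0, 1) * (1 - tx) + corner(1, 0, 1) * tx
    c11 = corner(0, 1, 1) * (1 - tx) + corner(1, 1, 1) * tx
    c0 = c00 * (1 - ty) + c10 * ty
    c1 = c01 * (1 - ty) + c11 * ty
    out = c0 * (1 - tz) + c1 * tz
    out = np.where(inside, out, np.nan)
    if scalar:
        val = float(out[0])
        if np.isnan(val):
            return outside
        return val
    return out


# ---------------------------------------------------------------------------
# Planar map text format: one JSON header line + CSV matrix


def write_planar_map(dmap: PlanarDoseMap, path) -> None:
    """Write a planar dose map as a JSON header line followed by a CSV matrix.

    Lossless for values representable at 9 significant digits; NaN
    (invalid) pixels round-trip.
    """
    header = {
        "format": "spiralfilm-planar-map",
        "version": 1,
        "pitch_cm": [float(dmap.pitch[0]), float(dmap.pitch[1])],
        "origin_uv_cm": [float(dmap.origin_uv[0]), float(dmap.origin_uv[1])],
        "plane_label": dmap.plane_label,
        "units": "cGy",
        "shape": list(dmap.values.shape),
    }
    buf = io.StringIO()
    buf.write(json.dumps(header) + "\n")
    np.savetxt(buf, dmap.values, delimiter=",", fmt="%.8e")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_planar_map(path) -> PlanarDoseMap:
    """Read a planar dose map written by :func:`write_planar_map`."""
    with open(path) as fh:
        header_line = fh.readline()
        try:
            header = json.loads(header_line)
        except json.JSONDecodeError as exc:
            raise DoseFormatError(f"bad planar-map header: {exc}") from exc
        values = np.loadtxt(fh, delimiter=",", ndmin=2)
    expected = tuple(header.get("shape", values.shape))
    if tuple(values.shape) != expected:
        raise DoseFormatError(
            f"matrix shape {values.shape} does not match header {expected}"
        )
    return PlanarDoseMap(
        values=values,
        pitch=tuple(header["pitch_cm"]),
        origin_uv=tuple(header["origin_uv_cm"]),
        plane_label=header.get("plane_label", "film"),
    )
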