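"""Regions of interest and voxel-grid geometry.

Conventions
-----------
* Physical coordinates are micrometres, stored as ``(x, y, z)`` triples.
* Voxel arrays are indexed ``(z, y, x)``; pixel coordinates are 0-based with
  half-open ranges, ``x`` indexing columns and ``y`` rows.
* ``VolumeGeometry.origin_um`` is the physical position of the *corner* of
  voxel ``(0, 0, 0)``; voxel centres sit half a voxel further along each axis.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "VolumeGeometry",
    "ROI",
    "RectangleROI",
    "EllipseROI",
    "CircularSegmentROI",
    "corner_background_rois",
]


class GeometryError(ValueError):
    """Raised when an ROI or volume request is geometrically invalid."""


@dataclasses.dataclass(frozen=True)
class VolumeGeometry:
    """Calibration mapping between micrometre space and a ZYX voxel grid."""

    origin_um: Tuple[float, float, float]  # (x, y, z) of corner of voxel (0,0,0)
    voxel_xy_um: float
    voxel_z_um: float
    shape: Tuple[int, int, int]  # (nz, ny, nx)

    def __post_init__(self) -> None:
        if self.voxel_xy_um <= 0 or self.voxel_z_um <= 0:
            raise GeometryError("voxel sizes must be positive")

    @property
    def n_voxels(self) -> int:
        nz, ny, nx = self.shape
        return nz * ny * nx

    def index_of(self, points_um: np.ndarray) -> np.ndarray:
        """Map (N, 3) xyz points to integer (N, 3) ``(iz, iy, ix)`` indices."""
        p = np.atleast_2d(np.asarray(points_um, dtype=float))
        ox, oy, oz = self.origin_um
        ix = np.floor((p[:, 0] - ox) / self.voxel_xy_um).astype(int)
        iy = np.floor((p[:, 1] - oy) / self.voxel_xy_um).astype(int)
        iz = np.floor((p[:, 2] - oz) / self.voxel_z_um).astype(int)
        return np.stack([iz, iy, ix], axis=1)

    def contains_index(self, idx: np.ndarray) -> np.ndarray:
        nz, ny, nx = self.shape
        return (
            (idx[:, 0] >= 0)
            & (idx[:, 0] < nz)
            & (idx[:, 1] >= 0)
            & (idx[:, 1] < ny)
            & (idx[:, 2] >= 0)
            & (idx[:, 2] < nx)
        )

    def voxel_centers_um(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis voxel-centre coordinate vectors ``(z, y, x)`` in µm."""
        ox, oy, oz = self.origin_um
        nz, ny, nx = self.shape
        zs = oz + (np.arange(nz) + 0.5) * self.voxel_z_um
        ys = oy + (np.arange(ny) + 0.5) * self.voxel_xy_um
        xs = ox + (np.arange(nx) + 0.5) * self.voxel_xy_um
        return zs, ys, xs

    def sphere_mask(self, center_um: Sequence[float], radius_um: float) -> np.ndarray:
        """Boolean ZYX mask of voxels whose centres lie inside a sphere."""
        zs, ys, xs = self.voxel_centers_um()
        cx, cy, cz = center_um
        dz2 = (zs - cz)[:, None, None] ** 2
        dy2 = (ys - cy)[None, :, None] ** 2
        dx2 = (xs - cx)[None, None, :] ** 2
        return dz2 + dy2 + dx2 <= radius_um**2


def _resolve_z(z_range: Optional[Tuple[int, int]], nz: int) -> Tuple[int, int]:
    if z_range is None:
        return 0, nz
    z0, z1 = int(z_range[0]), int(z_range[1])
    if z1 <= z0:
        raise GeometryError(f"empty z range ({z0}, {z1})")
    if z0 < 0 or z1 > nz:
        raise GeometryError(f"z range ({z0}, {z1}) outside stack of depth {nz}")
    return z0, z1


@dataclasses.dataclass(frozen=True)
class ROI:
    """Base region of interest: a 2D footprint plus an optional z range."""

    z_range: Optional[Tuple[int, int]] = None

    def footprint(self, shape_yx: Tuple[int, int]) -> np.ndarray:
        raise NotImplementedError

    def mask3d(self, shape_zyx: Tuple[int, int, int]) -> np.ndarray:
        nz, ny, nx = shape_zyx
        z0, z1 = _resolve_z(self.z_range, nz)
        fp = self.footprint((ny, nx))
        mask = np.zeros(shape_zyx, dtype=bool)
        mask[z0:z1] = fp
        return mask

    def area(self, shape_yx: Tuple[int, int]) -> int:
        return int(self.footprint(shape_yx).sum())

    def _check_nonempty(self, fp: np.ndarray) -> np.ndarray:
        if not fp.any():
            raise GeometryError(f"{type(self).__name__} has zero area in this image")
        return fp


@dataclasses.dataclass(frozen=True)
class RectangleROI(ROI):
    """Axis-aligned rectangle ``[x0, x1) × [y0, y1)`` in pixel coordinates."""

    x0: int = 0
    x1: int = 0
    y0: int = 0
    y1: int = 0

    def footprint(self, shape_yx: Tuple[int, int]) -> np.ndarray:
        ny, nx = shape_yx
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise GeometryError("rectangle has non-positive extent")
        if self.x0 < 0 or self.y0 < 0 or self.x1 > nx or self.y1 > ny:
            raise GeometryError("rectangle exceeds image bounds")
        fp = np.zeros(shape_yx, dtype=bool)
        fp[self.y0 : self.y1, self.x0 : self.x1] = True
        return self._check_nonempty(fp)


@dataclasses.dataclass(frozen=True)
class EllipseROI(ROI):
    """Ellipse with centre ``(cx, cy)`` and semi-axes ``(rx, ry)`` in pixels."""

    cx: float = 0.0
    cy: float = 0.0
    rx: float = 1.0
    ry: float = 1.0

    def footprint(self, shape_yx: Tuple[int, int]) -> np.ndarray:
        if self.rx <= 0 or self.ry <= 0:
            raise GeometryError("ellipse semi-axes must be positive")
        ny, nx = shape_yx
        y, x = np.ogrid[:ny, :nx]
        fp = ((x + 0.5 - self.cx) / self.rx) ** 2 + (
            (y + 0.5 - self.cy) / self.ry
        ) ** 2 <= 1.0
        return self._check_nonempty(fp)


@dataclasses.dataclass(frozen=True)
class CircularSegmentROI(ROI):
    """Circular segment: pixels inside a circle and on one side of a chord.

    A pixel centre ``p`` is kept when ``|p - c| <= radius`` and
    ``(p - c) · n >= offset``, with ``n = (nx_, ny_)`` the (unnormalised is
    fine) chord normal and ``offset`` the signed chord distance in pixels.
    This mirrors the chord-separated bleached/unbleached nucleus portions
    measured in FRAP quantitation.
    """

    cx: float = 0.0
    cy: float = 0.0
    radius: float = 1.0
    nx_: float = 1.0
    ny_: float = 0.0
    offset: float = 0.0

    def footprint(self, shape_yx: Tuple[int, int]) -> np.ndarray:
        if self.radius <= 0:
            raise GeometryError("segment radius must be positive")
        norm = float(np.hypot(self.nx_, self.ny_))
        if norm == 0:
            raise GeometryError("chord normal must be nonzero")
        ny, nx = shape_yx
        y, x = np.ogrid[:ny, :nx]
        dx = x + 0.5 - self.cx
        dy = y + 0.5 - self.cy
        inside = dx**2 + dy**2 <= self.radius**2
        side = (dx * self.nx_ + dy * self.ny_) / norm >= self.offset
        return self._check_nonempty(inside & side)


def corner_background_rois(
    shape_yx: Tuple[int, int], size: int = 8, n: int = 3
) -> list:
    """Small square ROIs in image corners, for background estimation.

    Mirrors the practice of drawing a few small reference ROIs outside the
    nuclei; callers must ensure the corners are signal-free.
    """
    ny, nx = shape_yx
    if size * 2 > min(ny, nx):
        raise GeometryError("background ROI size too large for image")
    corners = [
        RectangleROI(x0=0, x1=size, y0=0, y1=size),
        RectangleROI(x0=nx - size, x1=nx, y0=0, y1=size),
        RectangleROI(x0=0, x1=size, y0=ny - size, y1=ny),
        RectangleROI(x0=nx - size, x1=nx, y0=ny - size, y1=ny),
    ]
    return corners[:n]
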