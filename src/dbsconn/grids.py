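"""Axis-aligned voxel grids in RAS millimetre space.

All volumetric quantities in the package (E-fields, VATs, connectivity
profiles, parcellations) live on a :class:`GridSpec`: an isotropic,
axis-aligned grid whose world axes are RAS millimetres.  Point-to-voxel
binning is half-open — a point sitting exactly on a voxel boundary belongs
to the higher-index voxel — so that repeated lookups are unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class GridSpec:
    """A regular 3-D grid: ``shape`` voxels of ``voxel_size`` mm, with the
    lower corner of voxel (0,0,0) at world position ``origin``."""

    shape: tuple[int, int, int]
    voxel_size: float = 1.0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"grid shape must be three positive integers, got {self.shape}")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    # -- geometry ---------------------------------------------------------

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(self.voxel_size) ** 3

    @property
    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) world corners of the grid, mm."""
        lo = np.asarray(self.origin, dtype=float)
        hi = lo + np.asarray(self.shape, dtype=float) * self.voxel_size
        return lo, hi

    @property
    def affine(self) -> np.ndarray:
        """NIfTI-style affine mapping voxel index -> world mm (voxel centres)."""
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size
        aff[:3, 3] = np.asarray(self.origin) + self.voxel_size / 2.0
        return aff

    # -- point/voxel conversion ------------------------------------------

    def point_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map world points (N, 3) to integer voxel indices (N, 3).

        Half-open binning: a point on a voxel boundary maps to the
        higher-index voxel.  Indices may fall outside the grid; see
        :meth:`inside`.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.floor((pts - np.asarray(self.origin)) / self.voxel_size).astype(np.int64)

    def inside(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask: which world points fall inside the grid bounds."""
        idx = self.point_to_index(points)
        shp = np.asarray(self.shape)
        return np.all((idx >= 0) & (idx < shp), axis=1)

    def ravel_index(self, idx: np.ndarray) -> np.ndarray:
        """Flatten (N, 3) voxel indices to linear offsets (C order)."""
        idx = np.atleast_2d(np.asarray(idx))
        return np.ravel_multi_index((idx[:, 0], idx[:, 1], idx[:, 2]), self.shape)

    def voxel_centres(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape (*grid.shape*, 3)."""
        axes = [
            np.asarray(self.origin)[d] + (np.arange(self.shape[d]) + 0.5) * self.voxel_size
            for d in range(3)
        ]
        xx, yy, zz = np.meshgrid(*axes, indexing="ij")
        return np.stack([xx, yy, zz], axis=-1)


def resample_polyline(points: np.ndarray, step: float) -> np.ndarray:
    """Resample an ordered 3-D polyline at fixed arc-length steps (mm).

    The first and last points are always retained.  A degenerate polyline of
    zero length is returned unchanged.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 3:
        raise ValueError("polyline must be an (N>=2, 3) array")
    if not step > 0:
        raise ValueError("step must be > 0")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total == 0.0:
        return pts.copy()
    n_steps = int(np.floor(total / step))
    stations = np.arange(n_steps + 1) * step
    if stations[-1] < total:
        stations = np.concatenate([stations, [total]])
    out = np.empty((stations.size, 3))
    for d in range(3):
        out[:, d] = np.interp(stations, arc, pts[:, d])
    return out


def polyline_voxels(points: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Distinct linear voxel ids visited by a (resampled) polyline.

    Points outside the grid are ignored.  Order of first visit is preserved
    but callers should treat the result as a set.
    """
    pts = np.asarray(points, dtype=float)
    keep = grid.inside(pts)
    if not np.any(keep):
        return np.empty(0, dtype=np.int64)
    lin = grid.ravel_index(grid.point_to_index(pts[keep]))
    # np.unique sorts; stable "set" semantics are all we need
    return np.unique(lin)
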