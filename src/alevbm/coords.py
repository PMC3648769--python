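"""Coordinate spaces and transforms.

Two stereotaxic spaces are supported, related by the classic piecewise-affine
mapping (a small rotation about x combined with axis scalings that differ
above and below the AC plane), plus the voxel<->world mapping carried by a
4x4 affine.

Conventions (fixed for the whole package):

* world coordinates in mm, RAS orientation;
* voxel indices are 0-based;
* the piecewise branch is decided by the sign of the Talairach-side z, so the
  two directions are exact inverses of each other;
* nearest-voxel rounding is round-half-away-from-zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ValidationError

SPACE_TAL = "TAL"
SPACE_MNI = "MNI"
SPACE_WORLD = "world"
_SPACES = (SPACE_TAL, SPACE_MNI, SPACE_WORLD)

_ROT_RAD = 0.05

def _rot_x(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, s], [0.0, -s, c]])

# TAL = M @ MNI; scaling differs above/below the AC plane.
_M_UP = _rot_x(_ROT_RAD) @ np.diag([0.99, 0.97, 0.92])
_M_DOWN = _rot_x(_ROT_RAD) @ np.diag([0.99, 0.97, 0.84])
_M_UP_INV = np.linalg.inv(_M_UP)
_M_DOWN_INV = np.linalg.inv(_M_DOWN)


@dataclass(frozen=True)
class Point3:
    """A point in mm in a declared space."""

    x: float
    y: float
    z: float
    space: str = SPACE_WORLD

    def __post_init__(self):
        arr = np.array([self.x, self.y, self.z], dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValidationError(f"non-finite coordinate: {arr}")
        if self.space not in _SPACES:
            raise ValidationError(
                f"unknown space {self.space!r}; expected one of {_SPACES}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


def mni2tal_array(xyz: np.ndarray) -> np.ndarray:
    """Piecewise-affine map of (N, 3) MNI mm coordinates to Talairach mm.

    The branch is chosen on the output (Talairach) z so that
    :func:`tal2mni_array` is an exact inverse.
    """
    xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
    if not np.all(np.isfinite(xyz)):
        raise ValidationError("non-finite coordinates")
    up = xyz @ _M_UP.T
    down = xyz @ _M_DOWN.T
    # tolerance keeps rounding noise at an exact z = 0 on the upper branch
    below = up[:, 2] < -1e-9
    out = np.where(below[:, None], down, up)
    return out


def tal2mni_array(xyz: np.ndarray) -> np.ndarray:
    """Inverse piecewise-affine map of (N, 3) Talairach mm to MNI mm."""
    xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
    if not np.all(np.isfinite(xyz)):
        raise ValidationError("non-finite coordinates")
    below = xyz[:, 2] < 0
    out = np.where(below[:, None], xyz @ _M_DOWN_INV.T, xyz @ _M_UP_INV.T)
    return out


def mni2tal(p: Point3) -> Point3:
    if p.space != SPACE_MNI:
        raise ValidationError(f"mni2tal expects an MNI point, got {p.space!r}")
    x, y, z = mni2tal_array(p.as_array())[0]
    return Point3(x, y, z, SPACE_TAL)


def tal2mni(p: Point3) -> Point3:
    if p.space != SPACE_TAL:
        raise ValidationError(f"tal2mni expects a TAL point, got {p.space!r}")
    x, y, z = tal2mni_array(p.as_array())[0]
    return Point3(x, y, z, SPACE_MNI)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.trunc(x + np.copysign(0.5, x))


@dataclass(frozen=True)
class VolumeGrid:
    """A 3-D raster: voxel counts per axis plus a voxel-index->world-mm affine."""

    shape: tuple
    affine: np.ndarray = field(repr=False)

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ConfigurationError(f"bad grid shape {self.shape}")
        object.__setattr__(self, "shape", shape)
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4) or not np.all(np.isfinite(aff)):
            raise ConfigurationError("affine must be a finite 4x4 matrix")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ConfigurationError("singular affine")
        object.__setattr__(self, "affine", aff)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3 (|det| of the 3x3 affine block)."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Per-axis voxel spacing in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (N, 3) voxel indices to world mm coordinates."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray):
        """Map (N, 3) world mm to nearest voxel indices.

        Returns ``(indices, in_bounds)`` where ``in_bounds`` flags indices
        that fall inside the grid.
        """
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        cont = xyz @ inv[:3, :3].T + inv[:3, 3]
        idx = _round_half_away(cont).astype(int)
        in_bounds = np.all((idx >= 0) & (idx < np.array(self.shape)), axis=1)
        return idx, in_bounds

    def all_voxel_centers(self) -> np.ndarray:
        """World coordinates of every voxel center, shape (prod(shape), 3)."""
        ii, jj, kk = np.meshgrid(
            *[np.arange(s) for s in self.shape], indexing="ij"
        )
        ijk = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
        return self.voxel_to_world(ijk)


def isotropic_grid(shape, voxel_mm: float = 2.0, origin=None) -> VolumeGrid:
    """Convenience constructor: isotropic voxels, world origin at the grid center
    unless an explicit origin (world position of voxel (0,0,0)) is given."""
    shape = tuple(int(s) for s in shape)
    if origin is None:
        origin = [-(s - 1) * voxel_mm / 2.0 for s in shape]
    aff = np.eye(4)
    aff[:3, :3] *= voxel_mm
    aff[:3, 3] = origin
    return VolumeGrid(shape=shape, affine=aff)
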