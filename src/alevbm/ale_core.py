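"""Modeled-activation maps and the combined ALE map.

Each focus contributes a unit-mass isotropic 3-D Gaussian kernel scaled by
the per-focus weight 1/n_foci of its study, so every study's summed kernel
mass is one. Per-voxel values combine by the probabilistic union
1 - prod(1 - p_i), first within a study over its foci and then across
studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .coords import VolumeGrid
from .errors import ConfigurationError, ValidationError
from .foci_prep import MaskVolume, Study

log = logging.getLogger(__name__)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class KernelSpec:
    """Isotropic 3-D Gaussian kernel given by its FWHM in mm."""

    fwhm_mm: float = 10.0

    def __post_init__(self):
        if not (self.fwhm_mm > 0):
            raise ConfigurationError(f"fwhm must be > 0, got {self.fwhm_mm}")

    @property
    def sigma_mm(self) -> float:
        return self.fwhm_mm * FWHM_TO_SIGMA


@dataclass(frozen=True)
class ALEMap:
    grid: VolumeGrid
    values: np.ndarray = field(repr=False)
    n_studies: int = 0
    n_foci: int = 0

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != self.grid.shape:
            raise ValidationError("ALE values do not match the grid shape")
        if vals.min() < 0 or vals.max() >= 1:
            raise ValidationError("ALE values must lie in [0, 1)")
        object.__setattr__(self, "values", vals)


def _density(sq_dist_mm2: np.ndarray, sigma_mm: float) -> np.ndarray:
    norm = (2.0 * np.pi) ** 1.5 * sigma_mm**3
    return np.exp(-0.5 * sq_dist_mm2 / sigma_mm**2) / norm


def focus_probability(offset_mm, kernel: KernelSpec, voxel_volume: float, weight: float = 1.0):
    """Probability a single focus assigns to a voxel at the given offset.

    min(1, weight * phi(offset; sigma) * voxel_volume), with phi the
    trivariate isotropic Gaussian density; symmetric in the offset.
    """
    if not (0 < weight <= 1):
        raise ValidationError(f"weight must be in (0, 1], got {weight}")
    if not (voxel_volume > 0):
        raise ValidationError("voxel_volume must be > 0")
    offset = np.asarray(offset_mm, dtype=float)
    sq = np.sum(np.atleast_2d(offset) ** 2, axis=-1)
    p = np.minimum(1.0, weight * _density(sq, kernel.sigma_mm) * voxel_volume)
    return float(p[0]) if offset.ndim == 1 else p


def kernel_probability_matrix(points_a: np.ndarray, points_b: np.ndarray,
                              kernel: KernelSpec, voxel_volume: float) -> np.ndarray:
    """Unweighted per-focus probabilities phi(|a_i - b_j|) * V, shape (len(a), len(b))."""
    a = np.atleast_2d(np.asarray(points_a, dtype=float))
    b = np.atleast_2d(np.asarray(points_b, dtype=float))
    sq = np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=-1)
    return _density(sq, kernel.sigma_mm) * voxel_volume


def study_values_at(points: np.ndarray, foci_xyz: np.ndarray,
                    kernel: KernelSpec, voxel_volume: float) -> np.ndarray:
    """Per-study union map sampled at arbitrary world points.

    Each focus carries weight 1/n_foci; the study value at a point is
    1 - prod over foci of (1 - min(1, w * phi * V)).
    """
    n_foci = len(foci_xyz)
    if n_foci < 1:
        raise ValidationError("a study needs at least one focus")
    w = 1.0 / n_foci
    probs = np.minimum(
        1.0, w * kernel_probability_matrix(foci_xyz, points, kernel, voxel_volume)
    )
    return 1.0 - np.prod(1.0 - probs, axis=0)


def study_ma_map(study: Study, grid: VolumeGrid, kernel: KernelSpec) -> np.ndarray:
    """Modeled-activation volume of one study on the full grid."""
    foci_xyz = np.array([f.location.as_array() for f in study.foci])
    lo = foci_xyz.min(axis=0)
    hi = foci_xyz.max(axis=0)
    corners = grid.voxel_to_world(
        np.array([[0, 0, 0], [s - 1 for s in grid.shape]])
    )
    gmin, gmax = corners.min(axis=0), corners.max(axis=0)
    if np.any(lo < gmin) or np.any(hi > gmax):
        log.warning(
            "study %s has foci outside the grid; they contribute via their "
            "true offsets", study.study_id
        )
    centers = grid.all_voxel_centers()
    vals = study_values_at(centers, foci_xyz, kernel, grid.voxel_volume)
    return vals.reshape(grid.shape)


def union_across_studies(per_study_values: np.ndarray) -> np.ndarray:
    """1 - prod(1 - v) along axis 0."""
    return 1.0 - np.prod(1.0 - per_study_values, axis=0)


def ale_map(studies, grid: VolumeGrid, kernel: KernelSpec,
            mask: MaskVolume | None = None) -> ALEMap:
    """Combined ALE map: union over studies of the per-study union maps.

    When a mask is supplied the map is evaluated on mask voxels only and is
    exactly zero elsewhere. Invariant to study order.
    """
    studies = list(studies)
    if not studies:
        raise ValidationError("ale_map needs at least one study")
    if mask is not None and mask.grid.shape != grid.shape:
        raise ValidationError("mask grid does not match the evaluation grid")

    if mask is None:
        points = grid.all_voxel_centers()
    else:
        points = mask.foreground_centers()

    stack = np.empty((len(studies), len(points)))
    for i, st in enumerate(studies):
        foci_xyz = np.array([f.location.as_array() for f in st.foci])
        stack[i] = study_values_at(points, foci_xyz, kernel, grid.voxel_volume)
    flat = union_across_studies(stack)

    values = np.zeros(grid.shape)
    if mask is None:
        values = flat.reshape(grid.shape)
    else:
        values[mask.voxels] = flat
    return ALEMap(
        grid=grid,
        values=values,
        n_studies=len(studies),
        n_foci=sum(s.n_foci for s in studies),
    )
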