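"""Permutation null for ALE scores and single-threshold inference.

The null is built by re-placing the observed per-study focus counts
uniformly (with replacement) over the mask's voxel centers, recomputing the
mask-restricted ALE map for each permutation, and pooling every in-mask
voxel value. Inference compares the observed map against one critical score
taken from the pooled empirical distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .ale_core import ALEMap, KernelSpec, kernel_probability_matrix, union_across_studies
from .coords import VolumeGrid
from .errors import ConfigurationError, ValidationError
from .foci_prep import MaskVolume


@dataclass(frozen=True)
class NullDistribution:
    """Pooled in-mask null ALE values across permutations."""

    samples: np.ndarray = field(repr=False)
    n_perms: int = 0
    study_sizes: tuple = ()
    seed: int = 0

    def __post_init__(self):
        s = np.asarray(self.samples, dtype=float)
        if s.size == 0:
            raise ValidationError("null distribution is empty")
        if s.min() < 0 or s.max() >= 1:
            raise ValidationError("null samples must lie in [0, 1)")
        if self.n_perms < 1:
            raise ValidationError("n_perms must be >= 1")
        object.__setattr__(self, "samples", s)
        object.__setattr__(self, "study_sizes", tuple(int(n) for n in self.study_sizes))


@dataclass(frozen=True)
class CriticalScore:
    alpha: float
    value: float

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if not (0 <= self.value < 1):
            raise ValidationError("critical value must lie in [0, 1)")


@dataclass(frozen=True)
class ThresholdedMap:
    """Binary suprathreshold volume with its voxel count."""

    grid: VolumeGrid
    values: np.ndarray = field(repr=False)
    critical: CriticalScore | None = None

    @property
    def n_suprathreshold(self) -> int:
        return int(np.asarray(self.values).sum())


def null_ale_values(study_sizes, mask: MaskVolume, grid: VolumeGrid,
                    kernel: KernelSpec, rng: np.random.Generator,
                    kernel_matrix: np.ndarray | None = None) -> np.ndarray:
    """One permutation: in-mask ALE values for randomly re-placed foci.

    Foci are drawn independently and uniformly, with replacement, over mask
    voxel centers, keeping the observed per-study counts (and hence the
    1/n_foci weights).
    """
    study_sizes = [int(n) for n in study_sizes]
    if any(n < 1 for n in study_sizes) or not study_sizes:
        raise ValidationError("study sizes must all be >= 1")
    centers = mask.foreground_centers()
    m = len(centers)
    if kernel_matrix is None:
        kernel_matrix = kernel_probability_matrix(
            centers, centers, kernel, grid.voxel_volume
        )
    total = sum(study_sizes)
    idx = rng.integers(0, m, size=total)
    per_study = np.empty((len(study_sizes), m))
    start = 0
    for s, n in enumerate(study_sizes):
        rows = kernel_matrix[idx[start : start + n]]
        probs = np.minimum(1.0, rows / n)
        per_study[s] = 1.0 - np.prod(1.0 - probs, axis=0)
        start += n
    return union_across_studies(per_study)


def sample_null(study_sizes, mask: MaskVolume, grid: VolumeGrid,
                kernel: KernelSpec, n_perms: int, seed: int) -> NullDistribution:
    """Pooled permutation null of in-mask ALE values. Deterministic per seed."""
    if n_perms < 1:
        raise ValidationError("n_perms must be >= 1")
    if mask.n_voxels < 2:
        raise ConfigurationError("mask must contain at least 2 voxels")
    if mask.grid.shape != grid.shape:
        raise ValidationError("mask grid does not match the evaluation grid")
    rng = np.random.default_rng(seed)
    centers = mask.foreground_centers()
    kmat = kernel_probability_matrix(centers, centers, kernel, grid.voxel_volume)
    pooled = np.empty((n_perms, mask.n_voxels))
    for p in range(n_perms):
        pooled[p] = null_ale_values(
            study_sizes, mask, grid, kernel, rng, kernel_matrix=kmat
        )
    return NullDistribution(
        samples=pooled.ravel(),
        n_perms=n_perms,
        study_sizes=tuple(study_sizes),
        seed=seed,
    )


def critical_score(null: NullDistribution, alpha: float) -> CriticalScore:
    """Empirical (1 - alpha)-quantile of the pooled null, as the
    ceil((1 - alpha) * N)-th order statistic (1-based, inclusive)."""
    if not (0 < alpha < 1):
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    s = np.sort(null.samples)
    n = s.size
    k = max(1, math.ceil((1.0 - alpha) * n))
    return CriticalScore(alpha=alpha, value=float(s[k - 1]))


def threshold_ale(ale: ALEMap, critical: CriticalScore) -> ThresholdedMap:
    """Voxels with ALE strictly above the critical score."""
    supra = ale.values > critical.value
    return ThresholdedMap(grid=ale.grid, values=supra, critical=critical)
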