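"""Self-contained calibration and recovery experiments.

Each function runs one end-to-end check of the pipeline on synthetic data
and returns plain numbers: questionnaire scale arithmetic, the voxelwise
exceedance rate of the ALE permutation threshold on fresh null maps, the
voxelwise false-positive rate of the correlation stage under a null
covariate, the strictness of the cluster-extent filter, and recovery of an
implanted covariate effect. They are used by the acceptance suite and the
reporting script.
"""

from __future__ import annotations

import numpy as np

from . import ale_core, ale_inference, coords, questionnaire, synthetic_data
from .structural_correlation import (
    ClusterConfig,
    GMImageSet,
    StatMap,
    suprathreshold_clusters,
    voxelwise_slope_t,
)


def escale_arithmetic(mean_total: float = 91.6, sd_total: float = 13.3) -> dict:
    """Per-item mean/SD implied by cohort-level totals, plus the item count
    enforced by the questionnaire key validator."""
    key = questionnaire.default_key()  # validator guarantees 22 + 3 items
    n_items = len(key.polarity)
    # the per-item statistics are the linear rescaling totals -> totals / 25,
    # identical to what cohort_descriptives applies to real totals
    probe = questionnaire.cohort_descriptives([mean_total - sd_total,
                                               mean_total + sd_total])
    assert probe.mean_per_item == probe.mean_total / n_items
    return {
        "per_item_mean": round(mean_total / n_items, 2),
        "per_item_sd": round(sd_total / n_items, 2),
        "n_items": n_items,
    }


def ale_calibration(seed: int, n_perms: int = 1000, n_fresh: int = 200,
                    alpha: float = 0.01, n_studies: int = 10,
                    foci_per_study: int = 5) -> dict:
    """Exceedance rate of the pooled-null critical ALE score on fresh null maps.

    Toy ellipsoid mask (~500 voxels on a 2-mm grid), the stated per-study
    focus counts, a pooled null of ``n_perms`` permutations, then the
    fraction of in-mask voxels above the critical score on ``n_fresh``
    freshly generated null maps.
    """
    grid = coords.isotropic_grid((24, 24, 24), 2.0)
    mask = synthetic_data.make_toy_mask(grid, semi_axes_mm=(11.0, 10.0, 9.0))
    kernel = ale_core.KernelSpec(10.0)
    sizes = [foci_per_study] * n_studies
    null = ale_inference.sample_null(sizes, mask, grid, kernel,
                                     n_perms=n_perms, seed=seed)
    crit = ale_inference.critical_score(null, alpha)
    centers = mask.foreground_centers()
    kmat = ale_core.kernel_probability_matrix(centers, centers, kernel,
                                              grid.voxel_volume)
    rng = np.random.default_rng(seed + 1)  # fresh maps: new randomness
    fracs = np.empty(n_fresh)
    for i in range(n_fresh):
        vals = ale_inference.null_ale_values(sizes, mask, grid, kernel, rng,
                                             kernel_matrix=kmat)
        fracs[i] = np.mean(vals > crit.value)
    return {
        "exceedance_rate": float(fracs.mean()),
        "mc_se": float(fracs.std(ddof=1) / np.sqrt(n_fresh)),
        "alpha": alpha,
        "critical_value": crit.value,
        "n_mask_voxels": mask.n_voxels,
        "n_perms": n_perms,
        "n_fresh": n_fresh,
    }


def vbm_calibration(seed: int, n_subjects: int = 101, shape=(20, 20, 20),
                    n_reps: int = 50, p_voxel: float = 0.001) -> dict:
    """Voxelwise false-positive rate of the correlation stage under a null
    covariate on pure Gaussian-noise volumes."""
    grid = coords.isotropic_grid(shape, 2.0)
    rng = np.random.default_rng(seed)
    fracs = np.empty(n_reps)
    for i in range(n_reps):
        images = rng.normal(size=(n_subjects, *grid.shape))
        covariate = rng.normal(size=n_subjects)
        stat = voxelwise_slope_t(GMImageSet(grid=grid, images=images),
                                 covariate)
        fracs[i] = np.mean(stat.p_values < p_voxel)
    return {
        "exceedance_rate": float(fracs.mean()),
        "mc_se": float(fracs.std(ddof=1) / np.sqrt(n_reps)),
        "p_voxel": p_voxel,
        "df": n_subjects - 2,
        "n_reps": n_reps,
    }


def _single_component_volume(grid: coords.VolumeGrid, size: int) -> np.ndarray:
    """A T-volume containing exactly one connected component of ``size``
    suprathreshold voxels (a filled 6x6 column stack)."""
    t = np.zeros(grid.shape)
    count = 0
    for k in range(grid.shape[2]):
        for i in range(6):
            for j in range(6):
                if count < size:
                    t[i, j, k] = 10.0
                    count += 1
    assert count == size
    return t


def extent_filter_probe(sizes=(149, 150, 151), df: int = 99) -> dict:
    """Largest single-component size still removed by the default extent
    filter (k > 150, strict)."""
    grid = coords.isotropic_grid((20, 20, 20), 2.0)
    cfg = ClusterConfig()
    rejected, retained = [], []
    for size in sizes:
        stat = StatMap(grid=grid, t_values=_single_component_volume(grid, size),
                       df=df)
        clusters = suprathreshold_clusters(stat, cfg)
        (retained if clusters else rejected).append(size)
    return {
        "largest_rejected": max(rejected),
        "rejected": rejected,
        "retained": retained,
        "k_min": cfg.k_min,
    }


def effect_recovery(seed: int, n_seeds: int = 50,
                    max_offset_voxels: int = 2) -> dict:
    """Fraction of seeded simulations in which the top cluster's peak lands
    within ``max_offset_voxels`` (per axis) of the implanted locus under the
    default thresholds."""
    hits = 0
    for i in range(n_seeds):
        cohort = synthetic_data.simulate_cohort(
            synthetic_data.CohortSimConfig(seed=seed + i)
        )
        scores = np.array([r.total_score for r in cohort], dtype=float)
        result = synthetic_data.simulate_gm_dataset(
            synthetic_data.GMSimConfig(seed=seed + 10_000 + i), scores
        )
        stat = voxelwise_slope_t(result.image_set, scores)
        clusters = suprathreshold_clusters(stat, ClusterConfig())
        if not clusters:
            continue
        grid = result.image_set.grid
        peak_idx, _ = grid.world_to_voxel(clusters[0].peak_world_mm.as_array())
        true_idx, _ = grid.world_to_voxel(result.locus_mm)
        if np.abs(peak_idx[0] - true_idx[0]).max() <= max_offset_voxels:
            hits += 1
    return {
        "success_rate": hits / n_seeds,
        "n_seeds": n_seeds,
        "max_offset_voxels": max_offset_voxels,
    }
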