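# alevbm

A small, tested pipeline for two coordinate/voxel-based neuroimaging
analyses, plus generators for every synthetic input it needs:

1. **Mask-restricted ALE meta-analysis** — activation foci from published
   studies are read from CSV, harmonized to MNI space (piecewise-affine
   Talairach conversion), filtered by a 5-mm tolerance to a binary region
   mask, blurred with unit-mass Gaussian kernels weighted 1/n_foci per
   study, and combined by the probabilistic union 1 − ∏(1 − pᵢ).
   Significance uses a single critical ALE score from a pooled permutation
   null (foci re-placed uniformly inside the mask, default 10,000
   permutations, α = 0.01).
2. **Voxelwise gray-matter–covariate correlation** — aligned gray-matter
   volumes are smoothed (6-mm FWHM default), intensity is regressed on a
   per-subject score voxel by voxel (T with df = n − 2, one-sided p), and
   results are thresholded at p < 0.001 combined with a strict
   cluster-extent rule (> 150 contiguous voxels, 18-connectivity default),
   with peak extraction and sphere-ROI overlap reporting.
3. **Questionnaire scoring** — a 25-item, 7-point Likert empathy scale
   (22 positive / 3 reverse-coded items), cohort descriptives, and a
   Kolmogorov–Smirnov normality check.

Note: the extent default follows the methods-level rule (k > 150); a figure
caption in the source publication states k > 1.0, which is surfaced here as
a configurable `--k-min`.

## Command line

All stages are subcommands of `alevbm`; every stage writes a JSON manifest
with its parameters and seed, and any two runs with the same config and
seed produce identical outputs.

```sh
alevbm simulate-foci  --out-dir sim --n-studies 10 --seed 1
alevbm ale            --foci sim/foci.csv --mask sim/mask.nii --out-dir ale_out
alevbm permtest       --foci sim/foci.csv --mask sim/mask.nii \
                      --out-dir perm_out --n-perms 10000 --alpha 0.01 --seed 1
alevbm simulate-gm    --out-dir gm --n-subjects 101 --seed 1
alevbm vbm            --images 'gm/gm_*.nii' --covariates gm/scores.csv \
                      --out-dir vbm_out --p-voxel 0.001 --k-min 150 \
                      --roi-center '-36 16 4' --roi-radius 10
alevbm simulate-cohort --out cohort.csv --seed 1
alevbm score          --responses cohort.csv --key cohort_key.csv --out totals.csv
alevbm overlap        --a vbm_out/clusters.nii --b roi.nii
```

Foci CSV dialect: `study_id, category, modality, space, x_mm, y_mm, z_mm,
n_subjects` with space tokens TAL/Talairach/MNI (case-insensitive).
Volumes are NIfTI-1; covariates/responses are plain CSV.

## Layout

| module | contents |
| --- | --- |
| `alevbm.coords` | TAL↔MNI piecewise-affine transforms, voxel↔world grids |
| `alevbm.foci_prep` | foci CSV I/O, harmonization, mask-tolerance filter, study grouping |
| `alevbm.ale_core` | kernels, per-study modeled-activation maps, ALE union |
| `alevbm.ale_inference` | pooled permutation null, critical score, thresholding |
| `alevbm.structural_correlation` | smoothing, voxelwise slope T, clusters, peaks, ROI overlap |
| `alevbm.questionnaire` | scale key, scoring, descriptives, KS normality |
| `alevbm.synthetic_data` | masks, foci tables, cohorts, gray-matter volumes with implanted effects |
| `alevbm.cli_io` | NIfTI/CSV I/O, manifests, the `alevbm` CLI |
| `alevbm.benchmarks` | calibration/recovery experiments used by the acceptance suite |
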