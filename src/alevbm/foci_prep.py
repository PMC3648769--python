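"""Foci tables: reading, space harmonization, mask-tolerance filtering, grouping.

The input dialect is a UTF-8 CSV with header
``study_id, category, modality, space, x_mm, y_mm, z_mm, n_subjects``.
Space tokens TAL | Talairach | MNI are accepted case-insensitively; the
writer emits the canonical TAL / MNI tokens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import coords
from .coords import Point3, VolumeGrid
from .errors import ConfigurationError, TableParseError, ValidationError

log = logging.getLogger(__name__)

CATEGORIES = ("physical_pain", "emotion", "empathy_for_pain", "motor", "other")
MODALITIES = ("fMRI", "PET")

_SPACE_ALIASES = {"tal": "TAL", "talairach": "TAL", "mni": "MNI"}
_MODALITY_ALIASES = {"fmri": "fMRI", "pet": "PET"}

REQUIRED_COLUMNS = (
    "study_id",
    "category",
    "modality",
    "space",
    "x_mm",
    "y_mm",
    "z_mm",
    "n_subjects",
)


@dataclass(frozen=True)
class Focus:
    """One reported activation peak."""

    study_id: str
    category: str
    modality: str
    space: str
    location: Point3
    n_subjects: int

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown category {self.category!r}")
        if self.modality not in MODALITIES:
            raise ValidationError(f"unknown modality {self.modality!r}")
        if self.space not in (coords.SPACE_TAL, coords.SPACE_MNI):
            raise ValidationError(f"unknown space {self.space!r}")
        if self.location.space != self.space:
            raise ValidationError("focus space label disagrees with its point")
        if int(self.n_subjects) < 1:
            raise ValidationError("n_subjects must be >= 1")


@dataclass(frozen=True)
class Study:
    """All surviving foci of one source study within one functional category.

    ``n_foci`` determines the per-focus kernel weight 1/n_foci, which is what
    keeps the study's total kernel mass at unity.
    """

    study_id: str
    category: str
    modality: str
    foci: tuple
    n_subjects: int

    def __post_init__(self):
        if len(self.foci) < 1:
            raise ValidationError("a study needs at least one focus")
        for f in self.foci:
            if f.study_id != self.study_id or f.category != self.category:
                raise ValidationError("study grouping is inconsistent")

    @property
    def n_foci(self) -> int:
        return len(self.foci)


@dataclass(frozen=True)
class MaskVolume:
    """A binary region mask bound to a grid."""

    grid: VolumeGrid
    voxels: np.ndarray = field(repr=False)

    def __post_init__(self):
        vox = np.asarray(self.voxels).astype(bool)
        if vox.shape != self.grid.shape:
            raise ConfigurationError(
                f"mask shape {vox.shape} != grid shape {self.grid.shape}"
            )
        if not vox.any():
            raise ConfigurationError("mask has no foreground voxels")
        object.__setattr__(self, "voxels", vox)

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def foreground_centers(self) -> np.ndarray:
        """World coordinates of foreground voxel centers, shape (n, 3)."""
        ijk = np.argwhere(self.voxels)
        return self.grid.voxel_to_world(ijk)


def read_foci_table(source) -> list:
    """Parse a foci CSV into a list of :class:`Focus`.

    Every malformed row is reported (with its 1-based data row number) in a
    single :class:`TableParseError`; nothing is silently skipped.
    """
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TableParseError([f"missing column(s): {', '.join(missing)}"])

    foci, errors = [], []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        problems = []
        space = _SPACE_ALIASES.get(str(row.space).strip().lower())
        if space is None:
            problems.append(f"unknown space token {row.space!r}")
        category = str(row.category).strip().lower()
        if category not in CATEGORIES:
            problems.append(f"unknown category {row.category!r}")
        modality = _MODALITY_ALIASES.get(str(row.modality).strip().lower())
        if modality is None:
            problems.append(f"unknown modality {row.modality!r}")
        xyz = []
        for col in ("x_mm", "y_mm", "z_mm"):
            raw = getattr(row, col)
            try:
                v = float(raw)
                if not np.isfinite(v):
                    raise ValueError
                xyz.append(v)
            except (TypeError, ValueError):
                problems.append(f"non-numeric {col} {raw!r}")
        try:
            n_subj = int(str(row.n_subjects).strip())
            if n_subj < 1:
                problems.append(f"n_subjects must be >= 1, got {n_subj}")
        except (TypeError, ValueError):
            problems.append(f"non-numeric n_subjects {row.n_subjects!r}")
            n_subj = None
        if problems:
            errors.append(f"row {i}: " + "; ".join(problems))
            continue
        foci.append(
            Focus(
                study_id=str(row.study_id).strip(),
                category=category,
                modality=modality,
                space=space,
                location=Point3(*xyz, space=space),
                n_subjects=n_subj,
            )
        )
    if errors:
        raise TableParseError(errors)
    return foci


def write_foci_table(foci, dest) -> None:
    """Write foci in the canonical CSV dialect (round-trips with the reader)."""
    df = pd.DataFrame(
        {
            "study_id": [f.study_id for f in foci],
            "category": [f.category for f in foci],
            "modality": [f.modality for f in foci],
            "space": [f.space for f in foci],
            "x_mm": [f.location.x for f in foci],
            "y_mm": [f.location.y for f in foci],
            "z_mm": [f.location.z for f in foci],
            "n_subjects": [f.n_subjects for f in foci],
        }
    )
    df.to_csv(dest, index=False)


def harmonize_space(foci) -> list:
    """Convert every TAL focus to MNI; MNI foci pass through unchanged."""
    out = []
    for f in foci:
        if f.space == coords.SPACE_TAL:
            p = coords.tal2mni(f.location)
            out.append(replace(f, space=coords.SPACE_MNI, location=p))
        else:
            out.append(f)
    return out


def mask_distances(foci, mask: MaskVolume) -> np.ndarray:
    """Euclidean distance (mm) from each focus to the nearest foreground
    voxel center of the mask. 0 for a focus coincident with a center."""
    centers = mask.foreground_centers()
    pts = np.array([f.location.as_array() for f in foci])
    if len(pts) == 0:
        return np.zeros(0)
    tree = cKDTree(centers)
    d, _ = tree.query(pts)
    return np.asarray(d, dtype=float)


def filter_to_mask(foci, mask: MaskVolume, tol_mm: float = 5.0):
    """Partition foci into (kept, excluded) by distance to the mask.

    A focus is kept iff its distance to the nearest foreground voxel center
    is <= ``tol_mm`` (boundary inclusive). Exclusions are logged with their
    distances; foci outside the grid are handled by the same distance rule,
    never dropped silently.
    """
    for f in foci:
        if f.space != coords.SPACE_MNI:
            raise ValidationError("filter_to_mask expects harmonized MNI foci")
    d = mask_distances(foci, mask)
    kept, excluded = [], []
    for f, dist in zip(foci, d):
        if dist <= tol_mm:
            kept.append(f)
        else:
            excluded.append(f)
            log.warning(
                "excluding focus %s (%s) at %.2f mm from mask (> %.1f mm)",
                f.study_id,
                f.category,
                dist,
                tol_mm,
            )
    survivors = {(f.study_id, f.category) for f in kept}
    for key in sorted({(f.study_id, f.category) for f in foci} - survivors):
        log.warning("study %s (%s) lost all its foci to the mask filter", *key)
    return kept, excluded


def group_into_studies(foci) -> list:
    """Group harmonized, filtered foci into Study records by (study_id, category).

    A publication contributing to two categories yields two Study records,
    so per-study normalization is per analysis. Conflicting n_subjects
    within one study_id is a validation error.
    """
    by_id = {}
    for f in foci:
        by_id.setdefault(f.study_id, set()).add(f.n_subjects)
    for sid, counts in by_id.items():
        if len(counts) > 1:
            raise ValidationError(
                f"study {sid!r} has conflicting n_subjects: {sorted(counts)}"
            )
    groups = {}
    for f in foci:
        groups.setdefault((f.study_id, f.category), []).append(f)
    studies = [
        Study(
            study_id=sid,
            category=cat,
            modality=members[0].modality,
            foci=tuple(members),
            n_subjects=members[0].n_subjects,
        )
        for (sid, cat), members in sorted(groups.items())
    ]
    return studies
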