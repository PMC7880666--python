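"""Tract ROI masks and mean-FA extraction from skeletonized volumes.

Each tract ROI is the intersection of its atlas label group with the
white-matter skeleton. When a patient has a focal lesion, the (binarized,
co-registered) lesion mask is subtracted from every ROI mask *and* the
whole-brain skeleton, and the same corrected masks are used for the patient
and every control, so patient and reference FA are sampled from identical
voxel sets. A tract emptied by the correction is flagged missing - the mean
over an empty voxel set is undefined - and excluded downstream.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import WHOLE_BRAIN, CohortFATable, SubjectRecord
from .volumes import BinaryMask, FAVolume, LabelVolume, VoxelGrid

__all__ = [
    "derive_skeleton",
    "ROISet",
    "build_roi_set",
    "apply_lesion_exclusion",
    "extract_mean_fa",
    "build_cohort_table",
    "SKELETON_THRESHOLD",
]

#: default mean-FA threshold defining skeleton voxels
SKELETON_THRESHOLD = 0.2


def derive_skeleton(mean_fa: FAVolume, threshold: float = SKELETON_THRESHOLD) -> BinaryMask:
    """Skeleton mask from a mean-FA volume: voxels with FA >= threshold.

    A convenience for when no precomputed skeleton mask is supplied; the
    upstream skeleton *projection* is never performed here.
    """
    return BinaryMask((mean_fa.data >= threshold).astype(np.uint8), mean_fa.grid)


@dataclass
class ROISet:
    """Named boolean ROI masks plus the whole-brain skeleton mask.

    ``mask_version`` records which lesion correction has been applied
    (None = uncorrected, otherwise the patient id whose lesion was
    subtracted). ROIs emptied by intersection/subtraction live in
    ``missing`` and have no mask entry.
    """

    grid: VoxelGrid
    masks: dict[str, np.ndarray]
    whole_brain: np.ndarray
    mask_version: str | None = None
    missing: frozenset[str] = frozenset()

    @property
    def names(self) -> list[str]:
        return list(self.masks)

    @property
    def voxel_counts(self) -> dict[str, int]:
        return {name: int(m.sum()) for name, m in self.masks.items()}


def build_roi_set(atlas: LabelVolume, skeleton: BinaryMask,
                  roi_names: Sequence[str] | None = None) -> ROISet:
    """Intersect each atlas label group with the skeleton mask.

    Requested label groups must be pairwise disjoint; an ROI with no
    skeleton voxel is flagged missing (never kept as an empty mask).
    """
    atlas.grid.require_match(skeleton.grid, "atlas and skeleton")
    names = list(roi_names) if roi_names is not None else list(atlas.name_map)
    unknown = [n for n in names if n not in atlas.name_map]
    if unknown:
        raise KeyError(f"unknown ROI names {unknown}; atlas defines {sorted(atlas.name_map)}")
    seen: dict[int, str] = {}
    for name in names:
        for lab in atlas.name_map[name]:
            if lab in seen:
                raise ValueError(
                    f"overlapping label groups: label {lab} in both {seen[lab]!r} and {name!r}"
                )
            seen[lab] = name
    masks: dict[str, np.ndarray] = {}
    missing = []
    for name in names:
        m = atlas.group_mask(name) & skeleton.data
        if not m.any():
            warnings.warn(f"ROI {name!r} has no skeleton voxel; flagged missing", stacklevel=2)
            missing.append(name)
        else:
            masks[name] = m
    return ROISet(grid=atlas.grid, masks=masks, whole_brain=skeleton.data.copy(),
                  mask_version=None, missing=frozenset(missing))


def apply_lesion_exclusion(rois: ROISet, lesion: BinaryMask, patient_id: str) -> ROISet:
    """Subtract a lesion mask from every ROI and the whole-brain skeleton."""
    rois.grid.require_match(lesion.grid, "ROI set and lesion mask")
    keep = ~lesion.data
    masks: dict[str, np.ndarray] = {}
    newly_missing = []
    for name, m in rois.masks.items():
        sub = m & keep
        if not sub.any():
            warnings.warn(
                f"ROI {name!r} fully covered by the lesion of {patient_id!r}; "
                "flagged missing and excluded from testing", stacklevel=2,
            )
            newly_missing.append(name)
        else:
            masks[name] = sub
    return ROISet(
        grid=rois.grid, masks=masks, whole_brain=rois.whole_brain & keep,
        mask_version=str(patient_id), missing=rois.missing | frozenset(newly_missing),
    )


def extract_mean_fa(fa: FAVolume, rois: ROISet) -> pd.Series:
    """Arithmetic mean FA over each ROI's voxels plus the whole-brain mean.

    Zero-valued voxels inside an ROI are skeleton voxels and are included;
    missing ROIs yield NaN.
    """
    fa.grid.require_match(rois.grid, "FA volume and ROI set")
    out: dict[str, float] = {}
    for name, mask in rois.masks.items():
        out[name] = float(fa.data[mask].mean())
    for name in rois.missing:
        out[name] = np.nan
    if rois.whole_brain.any():
        out[WHOLE_BRAIN] = float(fa.data[rois.whole_brain].mean())
    else:
        out[WHOLE_BRAIN] = np.nan
    return pd.Series(out, name="mean_fa")


def roi_set_to_labels(rois: ROISet) -> LabelVolume:
    """Flatten an ROISet into one labelled volume (QC export).

    ROIs get labels 1..k in name order; 0 is background. Lesion-corrected
    sets therefore visualize exactly the voxels that were sampled.
    """
    data = np.zeros(rois.grid.shape, dtype=np.int16)
    name_map: dict[str, frozenset[int]] = {}
    for lab, (name, mask) in enumerate(rois.masks.items(), start=1):
        data[mask] = lab
        name_map[name] = frozenset({lab})
    return LabelVolume(data, rois.grid, name_map=name_map)


def build_cohort_table(subjects: Iterable[SubjectRecord],
                       fa_volumes: Mapping[tuple[str, str] | str, FAVolume],
                       rois: ROISet,
                       lesion_masks: Mapping[str, BinaryMask] | None = None,
                       ) -> dict[str | None, CohortFATable]:
    """Extract mean-FA tables, one per lesion-corrected mask version.

    ``fa_volumes`` maps subject id (or ``(subject_id, timepoint)``) to its
    skeletonized FA volume. For every lesioned patient a dedicated table is
    built in which *both* that patient's rows and every control's row are
    computed on the patient-specific lesion-corrected masks; a patient's
    single lesion mask (e.g. delineated subacutely) is applied to all of
    that patient's timepoints. Lesion-free patients share the uncorrected
    table keyed ``None``.
    """
    subjects = list(subjects)
    lesion_masks = dict(lesion_masks or {})

    def volume_for(rec: SubjectRecord) -> FAVolume:
        for key in ((rec.subject_id, rec.timepoint), rec.subject_id):
            if key in fa_volumes:
                return fa_volumes[key]
        raise KeyError(f"no FA volume supplied for subject {rec.subject_id!r} "
                       f"(timepoint {rec.timepoint!r})")

    controls = [r for r in subjects if r.group == "control"]
    patients = [r for r in subjects if r.group == "patient"]

    def extract_rows(records: Sequence[SubjectRecord], roi_set: ROISet) -> CohortFATable:
        # rows built one record at a time so a longitudinal subject keeps one
        # row per timepoint under the same subject id
        rows = []
        for r in records:
            row = {"group": r.group, "age": r.age, "timepoint": r.timepoint}
            row.update(extract_mean_fa(volume_for(r), roi_set).to_dict())
            rows.append(row)
        frame = pd.DataFrame(rows, index=pd.Index([r.subject_id for r in records],
                                                  name="subject_id"))
        return CohortFATable(frame, mask_version=roi_set.mask_version)

    tables: dict[str | None, CohortFATable] = {}
    plain = [r for r in patients if r.subject_id not in lesion_masks]
    tables[None] = extract_rows(controls + plain, rois)
    for pid, lesion in lesion_masks.items():
        own = [r for r in patients if r.subject_id == pid]
        if not own:
            raise KeyError(f"lesion mask supplied for unknown patient {pid!r}")
        corrected = apply_lesion_exclusion(rois, lesion, pid)
        tables[pid] = extract_rows(controls + own, corrected)
    return tables
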