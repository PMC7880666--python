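"""Synthetic cohorts with the statistical structure the pipeline assumes.

Table-level generator: per-tract control mean FA follows a correlated
multivariate normal (equicorrelated tracts, tract-specific means and SDs)
with a linear + quadratic age trend; injured patients are control draws
shifted down by ``effect_size`` control-SDs in their affected tracts; the
whole-brain column is a voxel-weighted tract mean plus independent noise.

Voxel-level generator: tracts are disjoint boxes on a small grid, the
"skeleton" is a one-voxel-thick plane through each box, subject voxel FA is
the subject's tract-level value plus voxel noise on skeleton voxels (zero
elsewhere), and lesions are spheres. Extracting this dataset through
:mod:`tractdx.extraction` reproduces the table-level means up to voxel
noise, which makes every stage of the pipeline testable end to end.

All generators are pure functions of (config, seed).
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import DEFAULT_PANEL, WHOLE_BRAIN, CohortFATable, SubjectRecord
from .volumes import BinaryMask, FAVolume, LabelVolume, VoxelGrid

__all__ = [
    "SimulationConfig",
    "simulate_cohort_table",
    "simulate_longitudinal_cohort",
    "simulate_voxel_dataset",
    "VoxelDataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters of the synthetic cohorts.

    Defaults mirror a single-scanner normative study: 103 controls, tract
    mean FA spread over 0.45-0.75 with SDs 0.015-0.03, inter-tract
    correlation 0.5, ages uniform on 20-70 years with a -5e-4 FA/year
    linear decline, and injured patients losing ``effect_size`` control-SDs
    of FA in ``n_injured_rois`` randomly chosen tracts.
    """

    n_controls: int = 103
    n_patients: int = 40
    roi_names: tuple[str, ...] = DEFAULT_PANEL
    roi_means: tuple[float, ...] | None = None  # default linspace 0.45..0.75
    roi_sds: tuple[float, ...] | None = None    # default linspace 0.015..0.03
    correlation: float = 0.5
    age_range: tuple[float, float] = (20.0, 70.0)
    age_ref: float = 45.0            # age at which roi_means apply
    beta_age: float = -5e-4          # FA per year
    beta_age2: float = 0.0           # FA per year^2 (about age_ref)
    patient_age_offset: float = 0.0  # added years for patients (age-bias scenarios)
    n_injured_rois: int = 4
    effect_size: float = 4.0         # injury depth in control-SD units
    injured_fraction: float = 1.0    # fraction of patients carrying injury
    wskl_noise_sd: float = 0.005
    longitudinal_decline: float = 0.5   # extra loss at t2, in SD units, injured tracts
    longitudinal_noise: float = 0.3     # measurement noise between timepoints, SD units
    voxel_noise_sd: float = 0.05
    seed: int | None = None

    def __post_init__(self):
        m = len(self.roi_names)
        if self.roi_means is not None and len(self.roi_means) != m:
            raise ValueError("roi_means length must match roi_names")
        if self.roi_sds is not None and len(self.roi_sds) != m:
            raise ValueError("roi_sds length must match roi_names")
        if not -1.0 < self.correlation < 1.0:
            raise ValueError("|inter-ROI correlation| must be < 1")
        if self.n_injured_rois > m:
            raise ValueError("n_injured_rois exceeds the number of ROIs")

    @property
    def means(self) -> np.ndarray:
        if self.roi_means is not None:
            return np.asarray(self.roi_means, dtype=float)
        return np.linspace(0.45, 0.75, len(self.roi_names))

    @property
    def sds(self) -> np.ndarray:
        if self.roi_sds is not None:
            sds = np.asarray(self.roi_sds, dtype=float)
        else:
            sds = np.linspace(0.015, 0.03, len(self.roi_names))
        if (sds <= 0).any():
            raise ValueError("ROI SDs must be positive")
        return sds

    def correlation_matrix(self) -> np.ndarray:
        m = len(self.roi_names)
        R = np.full((m, m), self.correlation)
        np.fill_diagonal(R, 1.0)
        if np.linalg.eigvalsh(R).min() <= 0:
            raise ValueError("inter-ROI correlation matrix is not positive definite")
        return R


def _rng(config: SimulationConfig, seed: int | None) -> np.random.Generator:
    if seed is None:
        seed = config.seed
    return np.random.default_rng(seed)


def _draw_values(config: SimulationConfig, ages: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """Correlated tract FA draws with the age trend, clipped to (0,1)."""
    L = np.linalg.cholesky(config.correlation_matrix())
    n = len(ages)
    noise = rng.standard_normal((n, len(config.roi_names))) @ L.T
    da = ages[:, None] - config.age_ref
    vals = config.means + config.beta_age * da + config.beta_age2 * da ** 2 + noise * config.sds
    lo, hi = 1e-6, 1.0 - 1e-6
    n_clip = int(((vals < lo) | (vals > hi)).sum())
    if n_clip:
        warnings.warn(f"{n_clip} simulated FA values clipped into (0, 1)", stacklevel=3)
        vals = np.clip(vals, lo, hi)
    return vals


def _wskl(config: SimulationConfig, vals: np.ndarray, rng: np.random.Generator,
          weights: np.ndarray | None = None) -> np.ndarray:
    if weights is None:
        weights = np.ones(vals.shape[1])
    weights = weights / weights.sum()
    return vals @ weights + rng.normal(0.0, config.wskl_noise_sd, size=len(vals))


def _assemble(config: SimulationConfig, ids, groups, ages, timepoints, vals, wskl) -> CohortFATable:
    frame = pd.DataFrame(vals, columns=list(config.roi_names),
                         index=pd.Index(ids, name="subject_id"))
    frame.insert(0, "timepoint", timepoints)
    frame.insert(0, "age", ages)
    frame.insert(0, "group", groups)
    frame[WHOLE_BRAIN] = np.clip(wskl, 1e-6, 1 - 1e-6)
    return CohortFATable(frame)


def simulate_cohort_table(config: SimulationConfig, seed: int | None = None,
                          ) -> tuple[CohortFATable, pd.DataFrame]:
    """One cross-sectional cohort table plus ground-truth injury labels.

    Returns ``(table, truth)`` where ``truth`` is a patients x ROIs boolean
    frame marking the tracts carrying injected injury.
    """
    rng = _rng(config, seed)
    m = len(config.roi_names)
    ages_c = rng.uniform(*config.age_range, size=config.n_controls)
    ages_p = rng.uniform(*config.age_range, size=config.n_patients) + config.patient_age_offset
    vals_c = _draw_values(config, ages_c, rng)
    vals_p = _draw_values(config, ages_p, rng)

    truth = np.zeros((config.n_patients, m), dtype=bool)
    n_injured = int(round(config.injured_fraction * config.n_patients))
    for i in range(n_injured):
        hit = rng.choice(m, size=config.n_injured_rois, replace=False)
        truth[i, hit] = True
    vals_p = vals_p - config.effect_size * config.sds * truth

    ids_c = [f"con{i:03d}" for i in range(config.n_controls)]
    ids_p = [f"pat{i:03d}" for i in range(config.n_patients)]
    wskl = _wskl(config, np.vstack([vals_c, vals_p]), rng)
    table = _assemble(
        config,
        ids_c + ids_p,
        ["control"] * config.n_controls + ["patient"] * config.n_patients,
        np.concatenate([ages_c, ages_p]),
        ["single"] * (config.n_controls + config.n_patients),
        np.vstack([vals_c, vals_p]),
        wskl,
    )
    truth_df = pd.DataFrame(truth, index=pd.Index(ids_p, name="subject_id"),
                            columns=list(config.roi_names))
    return table, truth_df


def simulate_longitudinal_cohort(config: SimulationConfig, seed: int | None = None,
                                 ) -> tuple[CohortFATable, CohortFATable, CohortFATable, pd.DataFrame]:
    """Two patient timepoints plus a control table and ground truth.

    Returns ``(controls, t1, t2, truth)``. The second timepoint repeats the
    first subject's underlying values with independent measurement noise
    (``longitudinal_noise`` in SD units) and an extra
    ``longitudinal_decline``-SD drop in injured tracts; subject identity and
    age are preserved.
    """
    ss = np.random.SeedSequence(seed if seed is not None else config.seed)
    s_cohort, s_noise = ss.spawn(2)
    table, truth = simulate_cohort_table(config, seed=s_cohort)
    rng = np.random.default_rng(s_noise)

    controls = table.controls()
    t1 = table.patients()
    t1 = replace(t1, frame=t1.frame.assign(timepoint="subacute"))

    vals1 = t1.frame[list(config.roi_names)].to_numpy(dtype=float)
    eps = rng.standard_normal(vals1.shape) * config.longitudinal_noise * config.sds
    decline = config.longitudinal_decline * config.sds * truth.to_numpy()
    vals2 = np.clip(vals1 + eps - decline, 1e-6, 1 - 1e-6)
    # the whole-brain residual is a stable per-subject offset (skeleton
    # composition), so it carries over; only session noise is redrawn
    weights = np.full(vals1.shape[1], 1.0 / vals1.shape[1])
    resid1 = t1.frame[WHOLE_BRAIN].to_numpy(dtype=float) - vals1 @ weights
    wskl2 = (vals2 @ weights + resid1
             + rng.normal(0.0, config.longitudinal_noise * config.wskl_noise_sd,
                          size=len(vals2)))
    t2 = _assemble(
        config, t1.frame.index.tolist(), ["patient"] * len(t1),
        t1.frame["age"].to_numpy(), ["chronic"] * len(t1), vals2, wskl2,
    )
    return controls, t1, t2, truth


# ---------------------------------------------------------------------------
# voxel-level dataset
# ---------------------------------------------------------------------------

@dataclass
class VoxelDataset:
    """A fully synthetic voxel-level study: atlas, skeleton, FA maps, lesions."""

    atlas: LabelVolume
    skeleton: BinaryMask
    fa: dict[str, FAVolume]
    lesions: dict[str, BinaryMask]
    records: list[SubjectRecord]
    table: CohortFATable          # the tract-level values the voxels encode
    truth: pd.DataFrame
    roi_boxes: dict[str, tuple[slice, slice, slice]] = field(default_factory=dict)

    @property
    def participants(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [r.subject_id for r in self.records],
                "group": [r.group for r in self.records],
                "age": [r.age for r in self.records],
                "timepoint": [r.timepoint for r in self.records],
            }
        )


def _roi_boxes(shape: tuple[int, int, int], n_rois: int,
               ) -> list[tuple[slice, slice, slice]]:
    """Disjoint axis-aligned boxes (1-voxel gaps) tiling the grid."""
    counts = [1, 1, 1]
    while int(np.prod(counts)) < n_rois:
        counts[int(np.argmin(counts))] += 1
    edges = []
    for dim, c in zip(shape, counts):
        step = dim // c
        if step < 3:
            raise ValueError(f"grid {shape} too small for {n_rois} disjoint ROI boxes")
        edges.append([(k * step, (k + 1) * step - 1) for k in range(c)])  # 1-voxel gap
    cells = list(itertools.product(*edges))[:n_rois]
    return [tuple(slice(a, b) for a, b in cell) for cell in cells]


def sphere_mask(grid: VoxelGrid, center: Sequence[float], radius: float) -> BinaryMask:
    """A voxel sphere (in voxel units) used as a synthetic focal lesion."""
    idx = np.indices(grid.shape, dtype=float)
    d2 = sum((idx[i] - center[i]) ** 2 for i in range(3))
    return BinaryMask((d2 <= radius ** 2).astype(np.uint8), grid)


def simulate_voxel_dataset(config: SimulationConfig,
                           shape: tuple[int, int, int] = (32, 32, 32),
                           seed: int | None = None,
                           lesions: Mapping[str, tuple[Sequence[float], float]] | None = None,
                           ) -> VoxelDataset:
    """Synthesize skeletonized FA volumes realizing a simulated cohort.

    Each tract occupies a disjoint box; skeleton voxels are the box's middle
    z-plane. Subject voxel FA on a tract's skeleton is that subject's
    simulated tract value plus N(0, ``voxel_noise_sd``) noise, zero off the
    skeleton. ``lesions`` maps patient id to ``(center_xyz, radius)`` in
    voxel units.
    """
    ss = np.random.SeedSequence(seed if seed is not None else config.seed)
    s_table, s_voxel = ss.spawn(2)
    table, truth = simulate_cohort_table(config, seed=s_table)
    rng = np.random.default_rng(s_voxel)

    grid = VoxelGrid(shape, np.diag([2.0, 2.0, 2.0, 1.0]))
    boxes = _roi_boxes(shape, len(config.roi_names))
    labels = np.zeros(shape, dtype=np.int16)
    skeleton = np.zeros(shape, dtype=bool)
    name_map: dict[str, frozenset[int]] = {}
    roi_boxes: dict[str, tuple[slice, slice, slice]] = {}
    for lab, (name, box) in enumerate(zip(config.roi_names, boxes), start=1):
        labels[box] = lab
        zmid = (box[2].start + box[2].stop) // 2
        skeleton[box[0], box[1], zmid] = True
        name_map[name] = frozenset({lab})
        roi_boxes[name] = box
    atlas = LabelVolume(labels, grid, name_map=name_map)
    skel = BinaryMask(skeleton.astype(np.uint8), grid)

    roi_skel = {name: (atlas.group_mask(name) & skeleton) for name in config.roi_names}
    fa_maps: dict[str, FAVolume] = {}
    for sid, row in table.frame.iterrows():
        vol = np.zeros(shape)
        for name in config.roi_names:
            mask = roi_skel[name]
            vals = row[name] + rng.normal(0.0, config.voxel_noise_sd, size=int(mask.sum()))
            vol[mask] = np.clip(vals, 0.0, 1.0)
        fa_maps[sid] = FAVolume(vol, grid)

    lesion_masks: dict[str, BinaryMask] = {}
    for pid, (center, radius) in (lesions or {}).items():
        if pid not in table.frame.index:
            raise KeyError(f"lesion requested for unknown subject {pid!r}")
        lesion_masks[pid] = sphere_mask(grid, center, radius)

    records = [
        SubjectRecord(subject_id=str(sid), group=row["group"], age=float(row["age"]),
                      timepoint=row["timepoint"],
                      lesion_mask=str(sid) if sid in lesion_masks else None)
        for sid, row in table.frame.iterrows()
    ]
    return VoxelDataset(atlas=atlas, skeleton=skel, fa=fa_maps, lesions=lesion_masks,
                        records=records, table=table, truth=truth, roi_boxes=roi_boxes)


def write_voxel_dataset(dataset: VoxelDataset, out_dir: str | Path) -> Path:
    """Write a voxel dataset to disk (NIfTI volumes + TSV tables + truth JSON)."""
    import json

    from . import io as _io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _io.save_volume(dataset.atlas, out / "atlas.nii.gz")
    _io.save_volume(dataset.skeleton, out / "skeleton.nii.gz")
    (out / "fa").mkdir(exist_ok=True)
    for sid, vol in dataset.fa.items():
        _io.save_volume(vol, out / "fa" / f"{sid}.nii.gz")
    for pid, mask in dataset.lesions.items():
        _io.save_volume(mask, out / f"lesion_{pid}.nii.gz")
    dataset.participants.to_csv(out / "participants.tsv", sep="\t", index=False)
    _io.save_label_names({n: dataset.atlas.name_map[n] for n in dataset.atlas.name_map},
                         out / "labels.tsv")
    dataset.table.to_tsv(out / "mean_fa.tsv")
    truth = {pid: dataset.truth.columns[dataset.truth.loc[pid]].tolist()
             for pid in dataset.truth.index}
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return out
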