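"""Data-driven tract panel selection.

Candidate tracts (an ICBM-DTI-81-style catalog of ~46 regions) are screened
in three steps: (i) small tracts - below the median voxel count of the full
catalog - are excluded, because tensor fits and skeleton sampling are
unreliable in small regions; (ii) tracts whose test-retest ICC in repeat
healthy-control scans is not above a reliability threshold (default 0.6,
the conventional "good" cut) are excluded; (iii) the survivors are
intersected with a curated panel encoding the irreducibly manual criteria
(anatomical coverage of association/projection/commissural pathways and
clinical relevance). The default curated panel is the 10-ROI set
:data:`tractdx.cohort.DEFAULT_PANEL`.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import DEFAULT_PANEL
from .reliability import ICCReport

__all__ = ["TractCatalog", "filter_by_size", "select_panel", "SelectionResult"]

CATEGORIES = ("association", "projection", "commissural")


@dataclass
class TractCatalog:
    """Candidate tract ROIs with voxel counts and anatomical category."""

    frame: pd.DataFrame  # index: tract name; columns: n_voxels, category, clinical_priority

    def __post_init__(self):
        df = self.frame
        if "n_voxels" not in df.columns:
            raise ValueError("catalog needs an 'n_voxels' column")
        if df.index.has_duplicates:
            raise ValueError("catalog tract names must be unique")
        if (df["n_voxels"] <= 0).any():
            raise ValueError("voxel counts must be positive")
        if "category" in df.columns:
            bad = set(df["category"].dropna()) - set(CATEGORIES)
            if bad:
                raise ValueError(f"unknown tract categories {sorted(bad)}")
        if "clinical_priority" not in df.columns:
            df = df.assign(clinical_priority=False)
        self.frame = df

    @property
    def names(self) -> list[str]:
        return self.frame.index.tolist()

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TractCatalog":
        df = pd.read_csv(path, sep="\t")
        if "name" not in df.columns:
            raise ValueError(f"{path}: expected a 'name' column")
        return cls(df.set_index("name"))

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.frame.rename_axis("name").reset_index().to_csv(path, sep="\t", index=False)
        return path


def filter_by_size(catalog: TractCatalog) -> list[str]:
    """Retain tracts at least as large as the catalog-wide median voxel count.

    Strictly-smaller-than-median tracts are excluded; ties at the median are
    kept, so at least half the candidates always survive.
    """
    counts = catalog.frame["n_voxels"]
    if len(counts) < 2:
        raise ValueError("need at least 2 candidate tracts")
    median = float(np.median(counts.to_numpy(dtype=float)))
    return counts.index[counts >= median].tolist()


@dataclass
class SelectionResult:
    retained_by_size: list[str]
    retained_by_icc: list[str]
    panel: list[str]
    icc_threshold: float
    warnings: list[str]

    def to_dict(self) -> dict:
        return {
            "retained_by_size": self.retained_by_size,
            "retained_by_icc": self.retained_by_icc,
            "panel": self.panel,
            "icc_threshold": self.icc_threshold,
            "warnings": self.warnings,
        }


def select_panel(catalog: TractCatalog, icc_report: ICCReport,
                 icc_threshold: float = 0.6,
                 curated_panel: Sequence[str] = DEFAULT_PANEL) -> SelectionResult:
    """Apply the size -> reliability -> curation cascade.

    ``icc_report`` must cover every size-retained tract. An ICC exactly at
    the threshold is excluded (the rule is *above* the threshold). Curated
    tracts that did not survive the earlier filters are reported in
    ``warnings`` rather than silently resurrected.
    """
    by_size = filter_by_size(catalog)
    missing_icc = [t for t in by_size if t not in icc_report.values.index]
    if missing_icc:
        raise ValueError(f"ICC report does not cover size-retained tracts {missing_icc}")
    above = set(icc_report.retained(icc_threshold))
    by_icc = [t for t in by_size if t in above]
    notes = []
    panel = []
    for name in curated_panel:
        if name in by_icc:
            panel.append(name)
        else:
            reason = "failed the size filter" if name not in by_size else (
                f"ICC {icc_report.values.get(name, float('nan')):.3f} <= {icc_threshold}")
            notes.append(f"curated tract {name!r} {reason}")
    for msg in notes:
        warnings.warn(msg, stacklevel=2)
    return SelectionResult(
        retained_by_size=by_size, retained_by_icc=by_icc, panel=panel,
        icc_threshold=icc_threshold, warnings=notes,
    )
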