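"""Cohort-level containers: subject records and the subject x ROI mean-FA table."""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "WHOLE_BRAIN",
    "META_COLUMNS",
    "DEFAULT_PANEL",
    "SubjectRecord",
    "CohortFATable",
]

#: column name of the whole-brain skeleton mean (tested stand-alone, outside
#: the tract FDR family)
WHOLE_BRAIN = "WSKL"

#: covariate columns of a cohort table; everything else is a mean-FA column
META_COLUMNS = ("group", "age", "timepoint")

#: the default 10-ROI diagnostic panel: body/genu/splenium of the corpus
#: callosum, corticospinal tracts, corona radiata, inferior longitudinal
#: fasciculi (left/right each) and the middle cerebellar peduncle
DEFAULT_PANEL = (
    "CCB", "CCG", "CCS",
    "CST_L", "CST_R",
    "CR_L", "CR_R",
    "ILF_L", "ILF_R",
    "MCP",
)

GROUPS = ("control", "patient")
SCALES = ("raw", "age_residual", "rank_normalized")


@dataclass(frozen=True)
class SubjectRecord:
    """One participants-table row."""

    subject_id: str
    group: str
    age: float
    timepoint: str = "single"
    lesion_mask: str | None = None

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r} for {self.subject_id}; expected {GROUPS}")
        if not np.isfinite(self.age) or self.age <= 0:
            raise ValueError(f"age must be positive and finite, got {self.age!r} for {self.subject_id}")


@dataclass
class CohortFATable:
    """Subject x ROI mean-FA matrix with covariates.

    ``frame`` is indexed by subject id and holds the covariate columns
    (``group``, ``age``, ``timepoint``) followed by one mean-FA column per
    tract ROI plus the whole-brain skeleton column :data:`WHOLE_BRAIN`.
    Missing ROI means (e.g. a tract fully covered by a lesion) are NaN,
    never silently zero.
    """

    frame: pd.DataFrame
    scale: str = "raw"
    mask_version: str | None = None

    def __post_init__(self):
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        df = self.frame
        missing_meta = [c for c in ("group", "age") if c not in df.columns]
        if missing_meta:
            raise ValueError(f"cohort table missing covariate columns {missing_meta}")
        if "timepoint" not in df.columns:
            df = df.assign(timepoint="single")
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()]
            key = df.assign(_tp=df["timepoint"]).set_index("_tp", append=True).index
            if key.has_duplicates:
                raise ValueError(f"duplicate (subject_id, timepoint) rows: {sorted(set(dup))}")
        bad_group = set(df["group"]) - set(GROUPS)
        if bad_group:
            raise ValueError(f"unknown group tokens {sorted(bad_group)}")
        ages = pd.to_numeric(df["age"], errors="coerce")
        if ages.isna().any() or (ages <= 0).any():
            bad = df.index[~(ages > 0)].tolist()
            raise ValueError(f"ages must be positive numbers; offending subjects: {bad}")
        value_cols = [c for c in df.columns if c not in META_COLUMNS]
        if not value_cols:
            raise ValueError("cohort table has no ROI columns")
        vals = df[value_cols].to_numpy(dtype=float)
        if self.scale == "raw":
            finite = vals[np.isfinite(vals)]
            if finite.size and (finite.min() <= 0.0 or finite.max() >= 1.0):
                raise ValueError("raw-scale mean FA values must lie strictly in (0, 1)")
        self.frame = df

    # -- column / row views -------------------------------------------------
    @property
    def roi_names(self) -> list[str]:
        """Tract ROI columns (excludes covariates and the whole-brain column)."""
        return [c for c in self.frame.columns if c not in META_COLUMNS and c != WHOLE_BRAIN]

    @property
    def value_columns(self) -> list[str]:
        cols = list(self.roi_names)
        if WHOLE_BRAIN in self.frame.columns:
            cols.append(WHOLE_BRAIN)
        return cols

    @property
    def values_frame(self) -> pd.DataFrame:
        """Just the mean-FA columns (tracts + whole brain)."""
        return self.frame[self.value_columns]

    @property
    def ages(self) -> pd.Series:
        return self.frame["age"].astype(float)

    def subset(self, mask) -> "CohortFATable":
        return replace(self, frame=self.frame.loc[mask])

    def controls(self) -> "CohortFATable":
        return self.subset(self.frame["group"] == "control")

    def patients(self) -> "CohortFATable":
        return self.subset(self.frame["group"] == "patient")

    def timepoint(self, tp: str) -> "CohortFATable":
        return self.subset(self.frame["timepoint"] == tp)

    def __len__(self) -> int:
        return len(self.frame)

    # -- I/O ----------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.frame.rename_axis("subject_id").reset_index().to_csv(path, sep="\t", index=False)
        return path

    @classmethod
    def from_tsv(cls, path: str | Path, scale: str = "raw",
                 mask_version: str | None = None) -> "CohortFATable":
        df = pd.read_csv(path, sep="\t")
        if "subject_id" not in df.columns:
            raise ValueError(f"{path}: expected a 'subject_id' column")
        df = df.set_index("subject_id")
        return cls(df, scale=scale, mask_version=mask_version)

    @classmethod
    def from_records(cls, records: Iterable[SubjectRecord], values: pd.DataFrame,
                     scale: str = "raw", mask_version: str | None = None) -> "CohortFATable":
        """Assemble a table from participant records and a subject x ROI frame."""
        records = list(records)
        meta = pd.DataFrame(
            {
                "group": [r.group for r in records],
                "age": [r.age for r in records],
                "timepoint": [r.timepoint for r in records],
            },
            index=pd.Index([r.subject_id for r in records], name="subject_id"),
        )
        missing = meta.index.difference(values.index)
        if len(missing):
            raise ValueError(f"no mean-FA values for subjects: {sorted(missing)}")
        return cls(meta.join(values.loc[meta.index]), scale=scale, mask_version=mask_version)
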