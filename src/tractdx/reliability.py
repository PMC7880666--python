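"""Intraclass correlation from the two-way ANOVA decomposition.

Used for test-retest tract screening, cross-iteration reliability of
subsample diagnoses, and longitudinal agreement of z-scores/p-values.
Single-measure forms only:

* ``absolute`` - two-way random effects, absolute agreement, ICC(2,1):
  ``(MSB - MSE) / (MSB + (k-1) MSE + k (MSC - MSE) / n)``
* ``consistency`` - two-way mixed effects, consistency, ICC(3,1):
  ``(MSB - MSE) / (MSB + (k-1) MSE)``

where MSB/MSC/MSE are the between-subject, between-rater (column) and
residual mean squares of the n x k subject-by-rater matrix.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .cohort import CohortFATable

__all__ = ["icc", "ICCReport", "compute_icc"]

ICCModel = Literal["absolute", "consistency"]


def _mean_squares(Y: np.ndarray) -> tuple[float, float, float]:
    n, k = Y.shape
    grand = Y.mean()
    ss_subj = k * ((Y.mean(axis=1) - grand) ** 2).sum()
    ss_col = n * ((Y.mean(axis=0) - grand) ** 2).sum()
    ss_tot = ((Y - grand) ** 2).sum()
    ss_err = ss_tot - ss_subj - ss_col
    msb = ss_subj / (n - 1)
    msc = ss_col / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msb, msc, mse


def icc(matrix: np.ndarray, model: ICCModel = "absolute") -> float:
    """Single-measure ICC of an n-subjects x k-raters matrix.

    Degenerate inputs: a matrix with no variance at all returns NaN; zero
    within-subject variance with between-subject spread returns 1.
    """
    Y = np.asarray(matrix, dtype=float)
    if Y.ndim != 2:
        raise ValueError("ICC expects a 2-d subjects x raters matrix")
    n, k = Y.shape
    if n < 2 or k < 2:
        raise ValueError(f"ICC needs >= 2 subjects and >= 2 raters, got {n} x {k}")
    if np.isnan(Y).any():
        raise ValueError("ICC matrix contains missing values; drop incomplete subjects first")
    msb, msc, mse = _mean_squares(Y)
    if model == "consistency":
        denom = msb + (k - 1) * mse
    elif model == "absolute":
        denom = msb + (k - 1) * mse + k * (msc - mse) / n
    else:
        raise ValueError(f"unknown ICC model {model!r}")
    if denom <= 0:
        return np.nan
    return float((msb - mse) / denom)


@dataclass
class ICCReport:
    """Per-ROI ICC values from a repeated-measures cohort."""

    values: pd.Series
    model: ICCModel
    n_subjects: int
    n_timepoints: int

    def __post_init__(self):
        if (self.values.dropna() > 1 + 1e-12).any():
            raise ValueError("ICC values cannot exceed 1")

    def retained(self, threshold: float = 0.6) -> list[str]:
        """ROIs with ICC strictly above ``threshold`` (boundary excluded)."""
        return self.values.index[self.values > threshold].tolist()

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "n_subjects": self.n_subjects,
            "n_timepoints": self.n_timepoints,
            "icc": {k: (None if pd.isna(v) else float(v)) for k, v in self.values.items()},
        }


def compute_icc(longitudinal: CohortFATable, model: ICCModel = "absolute") -> ICCReport:
    """Test-retest ICC per ROI from a multi-timepoint cohort table.

    Subjects missing any timepoint (or with a missing ROI value) are dropped
    from that ROI's matrix with a warning.
    """
    df = longitudinal.frame
    timepoints = sorted(df["timepoint"].unique())
    if len(timepoints) < 2:
        raise ValueError("need at least 2 timepoints for test-retest ICC")
    values = {}
    n_used = 0
    for roi in longitudinal.value_columns:
        wide = df.pivot_table(index=df.index, columns="timepoint", values=roi, aggfunc="first")
        wide = wide.reindex(columns=timepoints)
        complete = wide.dropna()
        if len(complete) < len(wide):
            warnings.warn(
                f"ROI {roi!r}: dropped {len(wide) - len(complete)} subjects with "
                "incomplete timepoints", stacklevel=2,
            )
        if len(complete) < 2:
            values[roi] = np.nan
            continue
        values[roi] = icc(complete.to_numpy(), model=model)
        n_used = max(n_used, len(complete))
    return ICCReport(
        values=pd.Series(values, name="icc"),
        model=model, n_subjects=n_used, n_timepoints=len(timepoints),
    )
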