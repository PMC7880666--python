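"""Single-subject normative diagnostics on tract mean-FA values.

The statistical core: per-tract control reference (mean ``x_bar`` and SD
``rho``), patient deviation scores ``z = (x - x_bar) / rho``, two-tailed
p-values, Benjamini-Hochberg FDR across the tract family, a stand-alone
whole-brain skeleton test, and the subject-level classification rule
(abnormal = at least one tract with FDR-significant *lower* FA). Normality
of each tract's control distribution is screened with Shapiro-Wilk; tracts
that fail are rank-inverse normalized (controls and patient jointly) before
scoring. An optional quadratic age model removes normal-ageing FA decline
before scoring.

Implemented as scikit-learn style estimators (:class:`NormativeDiagnostic`,
:class:`AgeResidualizer`); the module-level functions are thin wrappers.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multitest import multipletests

from .cohort import META_COLUMNS, WHOLE_BRAIN, CohortFATable

__all__ = [
    "rank_inverse_normalize",
    "check_normality",
    "compute_reference",
    "ControlReference",
    "DiagnosticResult",
    "NormativeDiagnostic",
    "AgeResidualizer",
    "fit_age_model",
    "apply_age_model",
    "diagnose",
    "diagnose_cohort",
]

_FDR_METHODS = {"bh": "fdr_bh", "by": "fdr_by"}


# ---------------------------------------------------------------------------
# transforms and reference statistics
# ---------------------------------------------------------------------------

def rank_inverse_normalize(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform with Blom offsets.

    Each value is replaced by ``Phi^{-1}((r - 3/8) / (n + 1/4))`` where ``r``
    is its average rank (ties share the average rank). Order is preserved;
    the output of a continuous input is close to standard normal.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 3:
        raise ValueError("rank-inverse normalization needs a 1-d vector with n >= 3")
    if not np.all(np.isfinite(values)):
        raise ValueError("rank-inverse normalization requires finite values")
    if np.all(values == values[0]):
        raise ValueError("all values identical; rank-inverse transform undefined")
    ranks = stats.rankdata(values, method="average")
    return stats.norm.ppf((ranks - 0.375) / (values.size + 0.25))


def check_normality(controls: pd.DataFrame | CohortFATable, alpha_sw: float = 0.05) -> pd.DataFrame:
    """Shapiro-Wilk screen of each ROI's control distribution.

    Returns a frame indexed by ROI with columns ``statistic``, ``p`` and
    ``normal`` (False when p < ``alpha_sw``). Zero-variance ROIs are flagged
    non-normal with a warning.
    """
    if isinstance(controls, CohortFATable):
        controls = controls.values_frame
    if len(controls) < 3:
        raise ValueError(f"need at least 3 controls for a normality check, got {len(controls)}")
    rows = {}
    for name, col in controls.items():
        vals = col.to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size < 3:
            rows[name] = (np.nan, np.nan, False)
            continue
        if np.all(vals == vals[0]):
            warnings.warn(f"ROI {name!r} has zero variance among controls", stacklevel=2)
            rows[name] = (np.nan, 0.0, False)
            continue
        stat, p = stats.shapiro(vals)
        rows[name] = (stat, p, p >= alpha_sw)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["statistic", "p", "normal"])
    out.index.name = "roi"
    return out


@dataclass
class ControlReference:
    """Per-ROI control mean and SD used for z-scoring."""

    mean: pd.Series
    sd: pd.Series
    n: int
    scale: str = "raw"
    mask_version: str | None = None

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("a control reference needs at least 2 controls")
        if (self.sd <= 1e-12).any():
            bad = self.sd.index[self.sd <= 1e-12].tolist()
            raise ValueError(f"zero control variance in ROIs {bad}; z-scores undefined")


def compute_reference(controls: pd.DataFrame | CohortFATable) -> ControlReference:
    """Control mean and sample SD (n-1 denominator) per ROI."""
    scale, version = "raw", None
    if isinstance(controls, CohortFATable):
        scale, version = controls.scale, controls.mask_version
        controls = controls.values_frame
    if len(controls) < 2:
        raise ValueError("need at least 2 controls")
    if controls.isna().any().any():
        bad = controls.columns[controls.isna().any()].tolist()
        raise ValueError(f"missing control values in ROIs {bad} for this mask version")
    return ControlReference(
        mean=controls.mean(), sd=controls.std(ddof=1), n=len(controls),
        scale=scale, mask_version=version,
    )


# ---------------------------------------------------------------------------
# diagnostic result container
# ---------------------------------------------------------------------------

@dataclass
class DiagnosticResult:
    """Per-subject outcome of the normative pipeline.

    ``table`` is indexed by tract ROI with columns ``x`` (subject mean FA),
    ``z``, ``p_raw``, ``p_fdr``, ``abnormal`` (FDR-significant *and* z < 0),
    ``high_fa`` (FDR-significant with z > 0, reported but never counted as
    injury), ``transform`` ('none' or 'rank_inverse'), ``extreme_rank``
    (subject held the extreme rank inside a joint rank-inverse transform)
    and ``missing``. The whole-brain skeleton test is stand-alone
    (uncorrected) and excluded from the classification rule.
    """

    subject_id: str
    table: pd.DataFrame
    whole_brain: dict | None
    classification: str
    alpha: float
    n_controls: int
    scale: str = "raw"
    mask_version: str | None = None
    age_corrected: bool = False

    @property
    def abnormal_rois(self) -> list[str]:
        return self.table.index[self.table["abnormal"].fillna(False).astype(bool)].tolist()

    def to_dict(self) -> dict:
        tbl = self.table.reset_index().rename(columns={"index": "roi"})
        return {
            "subject_id": self.subject_id,
            "classification": self.classification,
            "alpha": self.alpha,
            "n_controls": self.n_controls,
            "scale": self.scale,
            "mask_version": self.mask_version,
            "age_corrected": self.age_corrected,
            "whole_brain": self.whole_brain,
            "rois": tbl.to_dict(orient="records"),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiagnosticResult":
        tbl = pd.DataFrame(d["rois"]).set_index("roi")
        return cls(
            subject_id=d["subject_id"], table=tbl, whole_brain=d["whole_brain"],
            classification=d["classification"], alpha=d["alpha"],
            n_controls=d["n_controls"], scale=d["scale"],
            mask_version=d["mask_version"], age_corrected=d["age_corrected"],
        )


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

class NormativeDiagnostic(BaseEstimator):
    """Normative z-score classifier of single subjects against a control cohort.

    Parameters
    ----------
    alpha : float
        Significance level for the FDR-corrected tract tests and the
        stand-alone whole-brain test.
    alpha_sw : float
        Shapiro-Wilk level below which a tract's control distribution is
        treated as non-normal.
    transform : {'auto', 'always', 'never'}
        Rank-inverse normalization policy. 'auto' transforms only tracts
        flagged non-normal at fit time; the transform is applied to the
        controls and the tested subject jointly.
    tail : {'normal', 't'}
        Reference distribution for the two-tailed p-value: standard normal
        (default) or Student t with n-1 degrees of freedom.
    fdr_method : {'bh', 'by'}
        Benjamini-Hochberg (default) or Benjamini-Yekutieli step-up.
    whole_brain_col : str
        Column treated as the whole-brain skeleton summary, tested alone at
        ``alpha`` (uncorrected) and excluded from the FDR family and from the
        subject classification rule.

    After :meth:`fit`: ``roi_names_`` (tract family), ``mean_``, ``sd_``,
    ``n_``, ``normality_`` (Shapiro-Wilk screen), ``transform_rois_``.
    """

    def __init__(self, alpha: float = 0.05, alpha_sw: float = 0.05,
                 transform: Literal["auto", "always", "never"] = "auto",
                 tail: Literal["normal", "t"] = "normal",
                 fdr_method: Literal["bh", "by"] = "bh",
                 whole_brain_col: str = WHOLE_BRAIN):
        self.alpha = alpha
        self.alpha_sw = alpha_sw
        self.transform = transform
        self.tail = tail
        self.fdr_method = fdr_method
        self.whole_brain_col = whole_brain_col

    # -- fitting ------------------------------------------------------------
    def fit(self, X: pd.DataFrame | CohortFATable, y=None) -> "NormativeDiagnostic":
        """Fit the control reference. ``X`` holds one row per control."""
        scale, version = "raw", None
        if isinstance(X, CohortFATable):
            scale, version = X.scale, X.mask_version
            X = X.values_frame
        X = pd.DataFrame(X)
        X = X[[c for c in X.columns if c not in META_COLUMNS]]
        if len(X) < 2:
            raise ValueError("need at least 2 controls to fit a reference")
        dropped = X.columns[X.isna().any()].tolist()
        if dropped:
            warnings.warn(
                f"ROIs with missing control values dropped from the reference: {dropped}",
                stacklevel=2,
            )
            X = X.drop(columns=dropped)
        self.scale_, self.mask_version_ = scale, version
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.roi_names_ = [c for c in X.columns if c != self.whole_brain_col]
        if not self.roi_names_:
            raise ValueError("no tract ROIs to test (empty family)")
        self.controls_ = X.copy()
        self.mean_ = X.mean()
        self.sd_ = X.std(ddof=1)
        if (self.sd_ <= 1e-12).any():  # numerically zero variance
            bad = self.sd_.index[self.sd_ <= 1e-12].tolist()
            raise ValueError(f"zero control variance in ROIs {bad}")
        self.n_ = len(X)
        if self.transform == "never":
            self.normality_ = None
            self.transform_rois_ = []
        else:
            self.normality_ = check_normality(X, alpha_sw=self.alpha_sw)
            if self.transform == "always":
                self.transform_rois_ = list(X.columns)
            else:
                self.transform_rois_ = self.normality_.index[~self.normality_["normal"]].tolist()
        return self

    @property
    def reference_(self) -> ControlReference:
        return ControlReference(self.mean_, self.sd_, self.n_,
                                scale=self.scale_, mask_version=self.mask_version_)

    # -- scoring ------------------------------------------------------------
    def _check_is_fitted(self):
        if not hasattr(self, "mean_"):
            raise RuntimeError("NormativeDiagnostic is not fitted; call fit(controls) first")

    def _coerce(self, X) -> pd.DataFrame:
        if isinstance(X, CohortFATable):
            X = X.values_frame
        X = pd.DataFrame(X)
        return X[[c for c in X.columns if c not in META_COLUMNS]]

    def _p_from_z(self, z: np.ndarray) -> np.ndarray:
        if self.tail == "t":
            return 2.0 * stats.t.sf(np.abs(z), df=self.n_ - 1)
        return 2.0 * stats.norm.sf(np.abs(z))

    def _score_arrays(self, X: pd.DataFrame):
        """Numpy z/extreme matrices for a coerced subject frame."""
        cols = list(self.controls_.columns)
        missing_cols = [c for c in cols if c not in X.columns]
        if missing_cols:
            raise ValueError(f"subject frame lacks fitted ROI columns {missing_cols}")
        V = X[cols].to_numpy(dtype=float)
        Z = (V - self.mean_.to_numpy()) / self.sd_.to_numpy()
        extreme = np.zeros_like(Z, dtype=bool)
        ctrl_np = self.controls_.to_numpy()
        for roi in self.transform_rois_:
            j = cols.index(roi)
            ctrl = ctrl_np[:, j]
            cmin, cmax = ctrl.min(), ctrl.max()
            for i in range(V.shape[0]):
                x = V[i, j]
                if not np.isfinite(x):
                    continue
                t = rank_inverse_normalize(np.append(ctrl, x))
                Z[i, j] = (t[-1] - t[:-1].mean()) / t[:-1].std(ddof=1)
                extreme[i, j] = x <= cmin or x >= cmax
        return cols, V, Z, extreme

    def z_frame(self, X) -> pd.DataFrame:
        """Deviation scores for each subject row; columns follow the fit."""
        self._check_is_fitted()
        X = self._coerce(X)
        cols, _, Z, _ = self._score_arrays(X)
        return pd.DataFrame(Z, index=X.index, columns=cols)

    def diagnose_frame(self, X) -> pd.DataFrame:
        """Tidy per-(subject, ROI) results for a frame of subjects.

        Index: (subject, roi) with the whole-brain row included under the
        fitted ``whole_brain_col`` name and marked ``standalone``.
        """
        self._check_is_fitted()
        X = self._coerce(X)
        cols, _, Z, extreme = self._score_arrays(X)
        tract_idx = [cols.index(r) for r in self.roi_names_]
        n_subj, n_tract = Z.shape[0], len(tract_idx)

        Zt = Z[:, tract_idx]
        P = self._p_from_z(Zt)
        ok = np.isfinite(P)
        Pfdr = np.full_like(P, np.nan)
        for i in range(n_subj):
            row_ok = ok[i]
            if not row_ok.any():
                raise ValueError(f"subject {X.index[i]!r}: no testable ROI (all missing)")
            Pfdr[i, row_ok] = multipletests(P[i, row_ok],
                                            method=_FDR_METHODS[self.fdr_method])[1]
        sig = ok & (Pfdr <= self.alpha)
        abnormal = sig & (Zt < 0)
        high = sig & (Zt > 0)

        has_wb = self.whole_brain_col in cols
        rois_out = list(self.roi_names_) + ([self.whole_brain_col] if has_wb else [])
        n_out = len(rois_out)

        def tile(mat_t, wb_col=None, fill=np.nan):
            out = np.full((n_subj, n_out), fill, dtype=mat_t.dtype if fill is not np.nan else float)
            out[:, :n_tract] = mat_t
            if has_wb and wb_col is not None:
                out[:, n_tract] = wb_col
            return out

        blocks = {"z": tile(Zt), "p_raw": tile(P), "p_fdr": tile(Pfdr)}
        ab = np.zeros((n_subj, n_out), dtype=bool)
        hi = np.zeros((n_subj, n_out), dtype=bool)
        ab[:, :n_tract] = abnormal
        hi[:, :n_tract] = high
        ext = np.zeros((n_subj, n_out), dtype=bool)
        ext[:, :n_tract] = extreme[:, tract_idx]
        if has_wb:
            jw = cols.index(self.whole_brain_col)
            zw = Z[:, jw]
            pw = np.where(np.isfinite(zw), self._p_from_z(zw), np.nan)
            blocks["z"][:, n_tract] = zw
            blocks["p_raw"][:, n_tract] = pw
            wb_sig = np.isfinite(pw) & (pw <= self.alpha)
            ab[:, n_tract] = wb_sig & (zw < 0)
            hi[:, n_tract] = wb_sig & (zw > 0)
            ext[:, n_tract] = extreme[:, jw]
        miss = ~np.isfinite(blocks["z"])
        standalone = np.zeros((n_subj, n_out), dtype=bool)
        if has_wb:
            standalone[:, n_tract] = True
        transform = np.array([
            "rank_inverse" if r in self.transform_rois_ else "none" for r in rois_out
        ], dtype=object)

        index = pd.MultiIndex.from_product([X.index, rois_out], names=["subject", "roi"])
        return pd.DataFrame(
            {
                "z": blocks["z"].ravel(), "p_raw": blocks["p_raw"].ravel(),
                "p_fdr": blocks["p_fdr"].ravel(), "abnormal": ab.ravel(),
                "high_fa": hi.ravel(),
                "transform": np.tile(transform, n_subj),
                "extreme_rank": ext.ravel(), "missing": miss.ravel(),
                "standalone": standalone.ravel(),
            },
            index=index,
        )

    def predict(self, X) -> np.ndarray:
        """Subject classification: 'abnormal' iff >= 1 tract is abnormal."""
        frame = self.diagnose_frame(X)
        tracts = frame[~frame["standalone"]]
        flag = tracts.groupby(level="subject", sort=False)["abnormal"].any()
        X = self._coerce(X)
        return np.where(flag.reindex(X.index).to_numpy(), "abnormal", "normal")

    def diagnose(self, X, age_corrected: bool = False) -> list[DiagnosticResult]:
        """Full :class:`DiagnosticResult` per subject row."""
        Xc = self._coerce(X)
        frame = self.diagnose_frame(X)
        results = []
        for subj in Xc.index:
            sub = frame.xs(subj, level="subject")
            tracts = sub[~sub["standalone"]].drop(columns="standalone")
            tracts = tracts.copy()
            tracts.insert(0, "x", Xc.loc[subj, tracts.index].to_numpy(dtype=float))
            wb = None
            if self.whole_brain_col in sub.index:
                row = sub.loc[self.whole_brain_col]
                wb = {
                    "x": float(Xc.at[subj, self.whole_brain_col]),
                    "z": float(row["z"]),
                    "p_raw": float(row["p_raw"]),
                    "abnormal": bool(row["abnormal"]),
                    "high_fa": bool(row["high_fa"]),
                }
            classification = "abnormal" if tracts["abnormal"].any() else "normal"
            results.append(DiagnosticResult(
                subject_id=str(subj), table=tracts, whole_brain=wb,
                classification=classification, alpha=self.alpha, n_controls=self.n_,
                scale=self.scale_, mask_version=self.mask_version_,
                age_corrected=age_corrected,
            ))
        return results


# ---------------------------------------------------------------------------
# age correction
# ---------------------------------------------------------------------------

class AgeResidualizer(TransformerMixin, BaseEstimator):
    """Remove the normal-ageing FA trend by quadratic regression.

    Fits, per ROI, ordinary least squares of mean FA on ``[1, age, age^2]``
    and replaces values by residuals; subjects transformed later (e.g. a
    patient) use the same coefficients. ``X`` must contain the ``age_col``
    alongside the ROI columns; the age column is dropped from the output
    unless ``keep_age`` is set.
    """

    def __init__(self, age_col: str = "age", quadratic: bool = True, keep_age: bool = False):
        self.age_col = age_col
        self.quadratic = quadratic
        self.keep_age = keep_age

    def _design(self, age: np.ndarray) -> np.ndarray:
        cols = [np.ones_like(age), age]
        if self.quadratic:
            cols.append(age ** 2)
        return np.column_stack(cols)

    def fit(self, X: pd.DataFrame, y=None) -> "AgeResidualizer":
        X = pd.DataFrame(X)
        if self.age_col not in X.columns:
            raise ValueError(f"age column {self.age_col!r} not in input")
        value_cols = [c for c in X.columns if c not in META_COLUMNS and c != self.age_col]
        if len(X) < 4:
            raise ValueError("need at least 4 subjects to fit the age model")
        age = X[self.age_col].to_numpy(dtype=float)
        D = self._design(age)
        if np.linalg.matrix_rank(D) < D.shape[1]:
            raise ValueError("degenerate age design (e.g. all subjects the same age)")
        Y = X[value_cols].to_numpy(dtype=float)
        coef, *_ = np.linalg.lstsq(D, Y, rcond=None)
        names = ["const", "age"] + (["age2"] if self.quadratic else [])
        self.coef_ = pd.DataFrame(coef, index=names, columns=value_cols)
        self.feature_names_in_ = np.asarray(value_cols, dtype=object)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "coef_"):
            raise RuntimeError("AgeResidualizer is not fitted")
        X = pd.DataFrame(X)
        if self.age_col not in X.columns:
            raise ValueError(f"age column {self.age_col!r} not in input")
        age = X[self.age_col].to_numpy(dtype=float)
        D = self._design(age)
        cols = list(self.coef_.columns)
        resid = X[cols].to_numpy(dtype=float) - D @ self.coef_.to_numpy()
        out = pd.DataFrame(resid, index=X.index, columns=cols)
        if self.keep_age:
            out.insert(0, self.age_col, age)
        return out


def fit_age_model(table: CohortFATable, fit_cohort: Literal["controls_only", "pooled"] = "controls_only",
                  quadratic: bool = True) -> AgeResidualizer:
    """Fit the quadratic age model on the control or pooled cohort."""
    sub = table.controls() if fit_cohort == "controls_only" else table
    model = AgeResidualizer(quadratic=quadratic)
    model.fit(sub.frame[["age"] + sub.value_columns])
    model.fit_cohort_ = fit_cohort
    return model


def apply_age_model(table: CohortFATable, model: AgeResidualizer) -> CohortFATable:
    """Replace mean-FA columns by age-model residuals (scale 'age_residual')."""
    resid = model.transform(table.frame[["age"] + table.value_columns])
    frame = table.frame.copy()
    frame[list(resid.columns)] = resid
    return CohortFATable(frame, scale="age_residual", mask_version=table.mask_version)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def diagnose(patient_row: pd.Series | pd.DataFrame, controls: pd.DataFrame | CohortFATable,
             alpha: float = 0.05, **estimator_kwargs) -> DiagnosticResult:
    """Diagnose a single subject row against a control frame."""
    est = NormativeDiagnostic(alpha=alpha, **estimator_kwargs).fit(controls)
    if isinstance(patient_row, pd.Series):
        patient_row = patient_row.to_frame().T
    return est.diagnose(patient_row)[0]


def diagnose_cohort(table: CohortFATable, alpha: float = 0.05,
                    age_correct: Literal["none", "controls", "pooled"] = "none",
                    **estimator_kwargs) -> list[DiagnosticResult]:
    """Diagnose every patient in a cohort table against its controls."""
    if age_correct != "none":
        cohort = {"controls": "controls_only", "pooled": "pooled"}[age_correct]
        table = apply_age_model(table, fit_age_model(table, fit_cohort=cohort))
    est = NormativeDiagnostic(alpha=alpha, **estimator_kwargs).fit(table.controls())
    patients = table.patients()
    if not len(patients):
        raise ValueError("cohort table contains no patients")
    return est.diagnose(patients, age_corrected=age_correct != "none")
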