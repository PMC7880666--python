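"""Validation machinery for the normative pipeline.

Three experiments:

* :func:`subsample_experiment` - how diagnosis degrades with a smaller
  control cohort: repeatedly subsample the controls, rediagnose every
  patient, apply the consensus rule (a tract is abnormal at a given size
  when flagged in strictly more than ``consensus_frac`` of iterations), and
  score the consensus subject classification against the full-cohort
  classification (sensitivity, specificity, PPV, NPV) plus the
  cross-iteration ICC of FDR-corrected p-values.
* :func:`loo_control_specificity` - leave-one-out diagnosis of each healthy
  control against the remaining cohort; the subject-level false-positive
  rate estimates specificity.
* :func:`longitudinal_reliability` - agreement of z-scores, FDR p-values
  and classifications between two patient timepoints diagnosed against the
  same controls.

Note the subsample metrics treat the full-cohort diagnosis as ground truth:
they measure reliability relative to the full cohort, not accuracy against
pathology.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import WHOLE_BRAIN, CohortFATable
from .normative import DiagnosticResult, NormativeDiagnostic
from .reliability import icc

__all__ = [
    "SampleSizeEvalResult",
    "subsample_experiment",
    "LOOSpecificityResult",
    "loo_control_specificity",
    "LongitudinalReliability",
    "longitudinal_reliability",
]


def _confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    def ratio(a, b):
        return float(a) / b if b else float("nan")
    return {
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
    }


@dataclass
class SampleSizeEvalResult:
    """Outcome of the control-subsample experiment."""

    metrics: pd.DataFrame          # index: size; columns TP/FP/TN/FN + metrics
    icc_pvalues: pd.DataFrame      # index: size; columns: ROI; cross-iteration ICC of p_fdr
    consensus: dict[int, pd.DataFrame]  # size -> patients x ROIs consensus-abnormal flags
    reference_classification: pd.Series  # full-cohort subject classification
    sizes: tuple[int, ...]
    n_iterations: int
    consensus_frac: float
    seed: int | None
    n_zero_variance_redraws: int = 0

    def to_dict(self) -> dict:
        return {
            "sizes": list(self.sizes),
            "n_iterations": self.n_iterations,
            "consensus_frac": self.consensus_frac,
            "seed": self.seed,
            "n_zero_variance_redraws": self.n_zero_variance_redraws,
            "reference_classification": self.reference_classification.to_dict(),
            "metrics": self.metrics.reset_index().to_dict(orient="records"),
            "icc_pvalues": {str(s): {k: (None if pd.isna(v) else float(v)) for k, v in row.items()}
                            for s, row in self.icc_pvalues.iterrows()},
        }


def subsample_experiment(controls: CohortFATable, patients: CohortFATable,
                         sizes: Sequence[int] = (10, 20, 30, 40, 50),
                         n_iter: int = 100, consensus_frac: float = 0.05,
                         seed: int | None = None, alpha: float = 0.05,
                         **estimator_kwargs) -> SampleSizeEvalResult:
    """Sensitivity/specificity of reduced-control diagnosis vs the full cohort.

    Subsamples are drawn without replacement; the seed hierarchy is
    master seed -> per-size stream -> per-iteration stream, so results are
    bit-reproducible for a fixed seed and config. A subsample with a
    zero-variance ROI (impossible in continuous data, possible in
    pathological fixtures) is redrawn with a warning and counted.
    """
    n_controls = len(controls)
    sizes = tuple(int(s) for s in sizes)
    if any(s >= n_controls for s in sizes):
        raise ValueError(f"subsample sizes must be < control n = {n_controls}")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")

    full = NormativeDiagnostic(alpha=alpha, **estimator_kwargs).fit(controls)
    rois = full.roi_names_
    pat_frame = patients.values_frame
    pat_ids = pat_frame.index
    ref_class = pd.Series(full.predict(patients) == "abnormal", index=pat_ids,
                          name="abnormal_full_cohort")

    master = np.random.SeedSequence(seed)
    size_streams = master.spawn(len(sizes))
    ctrl_values = controls.values_frame
    threshold = consensus_frac * n_iter

    rows, icc_rows, consensus = [], [], {}
    n_redraws = 0
    for size, stream in zip(sizes, size_streams):
        abnormal_counts = np.zeros((len(pat_ids), len(rois)), dtype=int)
        pfdr_stack = np.empty((n_iter, len(pat_ids), len(rois)))
        for it, it_stream in enumerate(stream.spawn(n_iter)):
            rng = np.random.default_rng(it_stream)
            for _attempt in range(100):
                take = rng.choice(n_controls, size=size, replace=False)
                sub = ctrl_values.iloc[take]
                if (sub.std(ddof=1) > 0).all():
                    break
                n_redraws += 1
                warnings.warn(f"zero-variance control subsample at n={size}; redrawn",
                              stacklevel=2)
            else:  # pragma: no cover - requires a pathological cohort
                raise ValueError(f"could not draw a non-degenerate subsample of n={size}")
            est = NormativeDiagnostic(alpha=alpha, **estimator_kwargs).fit(sub)
            frame = est.diagnose_frame(pat_frame)
            tracts = frame[~frame["standalone"]]
            ab = tracts["abnormal"].to_numpy().reshape(len(pat_ids), len(rois))
            pf = tracts["p_fdr"].to_numpy().reshape(len(pat_ids), len(rois))
            abnormal_counts += ab
            pfdr_stack[it] = pf
        cons = abnormal_counts > threshold  # strictly more than consensus_frac * n_iter
        consensus[size] = pd.DataFrame(cons, index=pat_ids, columns=rois)
        subject_abnormal = cons.any(axis=1)
        ref = ref_class.to_numpy()
        tp = int((subject_abnormal & ref).sum())
        fp = int((subject_abnormal & ~ref).sum())
        tn = int((~subject_abnormal & ~ref).sum())
        fn = int((~subject_abnormal & ref).sum())
        rows.append({"size": size, "TP": tp, "FP": fp, "TN": tn, "FN": fn,
                     **_confusion_metrics(tp, fp, tn, fn)})
        # iterations act as raters, patients as subjects; iteration identity is
        # arbitrary, hence the consistency-type ICC
        icc_rows.append({
            "size": size,
            **{roi: icc(pfdr_stack[:, :, j].T, model="consistency")
               for j, roi in enumerate(rois)},
        })

    return SampleSizeEvalResult(
        metrics=pd.DataFrame(rows).set_index("size"),
        icc_pvalues=pd.DataFrame(icc_rows).set_index("size"),
        consensus=consensus,
        reference_classification=ref_class,
        sizes=sizes, n_iterations=n_iter, consensus_frac=consensus_frac,
        seed=seed, n_zero_variance_redraws=n_redraws,
    )


@dataclass
class LOOSpecificityResult:
    """Leave-one-out diagnosis of every control."""

    per_control: pd.DataFrame  # index: subject; classification, n_abnormal_tracts, wb flags
    results: list[DiagnosticResult] = field(repr=False)
    alpha: float = 0.05

    @property
    def subject_false_positive_rate(self) -> float:
        """Fraction of controls with >= 1 FDR-significant low-FA tract."""
        return float((self.per_control["classification"] == "abnormal").mean())

    @property
    def whole_brain_false_positive_rate(self) -> float:
        wb = self.per_control["whole_brain_abnormal"].dropna()
        return float(wb.mean()) if len(wb) else float("nan")

    @property
    def tract_false_positive_rate(self) -> float:
        """Abnormal tract flags as a fraction of all control-tract tests."""
        return float(self.per_control["n_abnormal_tracts"].sum()
                     / self.per_control["n_tracts"].sum())

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "n_controls": int(len(self.per_control)),
            "subject_false_positive_rate": self.subject_false_positive_rate,
            "whole_brain_false_positive_rate": self.whole_brain_false_positive_rate,
            "tract_false_positive_rate": self.tract_false_positive_rate,
            "per_control": self.per_control.reset_index().to_dict(orient="records"),
        }


def loo_control_specificity(controls: CohortFATable, alpha: float = 0.05,
                            **estimator_kwargs) -> LOOSpecificityResult:
    """Diagnose each control against the remaining n-1; summarize FP rates."""
    values = controls.values_frame
    if len(values) < 3:
        raise ValueError("leave-one-out specificity needs at least 3 controls")
    rows, results = [], []
    for subj in values.index:
        rest = values.drop(index=subj)
        est = NormativeDiagnostic(alpha=alpha, **estimator_kwargs).fit(rest)
        res = est.diagnose(values.loc[[subj]])[0]
        results.append(res)
        rows.append({
            "subject": subj,
            "classification": res.classification,
            "n_abnormal_tracts": len(res.abnormal_rois),
            "n_tracts": int((~res.table["missing"]).sum()),
            "whole_brain_abnormal": (res.whole_brain["abnormal"]
                                     if res.whole_brain is not None else np.nan),
        })
    per_control = pd.DataFrame(rows).set_index("subject")
    return LOOSpecificityResult(per_control=per_control, results=results, alpha=alpha)


@dataclass
class LongitudinalReliability:
    """Between-timepoint agreement of the diagnostic outputs."""

    icc_z: pd.Series
    icc_pfdr: pd.Series
    whole_brain_icc_z: float
    whole_brain_icc_p: float
    classifications: pd.DataFrame   # index: subject; columns t1, t2
    agreement: pd.DataFrame         # 2x2 classification counts
    icc_model: str

    def to_dict(self) -> dict:
        def ser(s):
            return {k: (None if pd.isna(v) else float(v)) for k, v in s.items()}
        return {
            "icc_model": self.icc_model,
            "icc_z": ser(self.icc_z),
            "icc_pfdr": ser(self.icc_pfdr),
            "whole_brain_icc_z": self.whole_brain_icc_z,
            "whole_brain_icc_p": self.whole_brain_icc_p,
            "classifications": self.classifications.reset_index().to_dict(orient="records"),
            "agreement": self.agreement.to_dict(),
        }


def longitudinal_reliability(timepoint1: CohortFATable, timepoint2: CohortFATable,
                             controls: CohortFATable, alpha: float = 0.05,
                             icc_model: str = "consistency",
                             **estimator_kwargs) -> LongitudinalReliability:
    """Reliability of diagnosis between two patient timepoints.

    Both timepoints are diagnosed against the same control reference; when
    lesions are present the caller must have built all three tables on the
    shared (first-timepoint) lesion-corrected masks, as recorded by their
    ``mask_version``.
    """
    ids1, ids2 = timepoint1.frame.index, timepoint2.frame.index
    if set(ids1) != set(ids2):
        raise ValueError(f"unmatched patients between timepoints: "
                         f"{sorted(set(ids1) ^ set(ids2))}")
    if timepoint1.mask_version != timepoint2.mask_version:
        raise ValueError("timepoints were extracted under different lesion masks; "
                         "apply the first-timepoint lesion mask to both")
    t2 = timepoint2.frame.loc[ids1]
    est = NormativeDiagnostic(alpha=alpha, **estimator_kwargs).fit(controls)
    f1 = est.diagnose_frame(timepoint1.values_frame)
    f2 = est.diagnose_frame(t2[timepoint2.value_columns])

    rois = est.roi_names_
    icc_z, icc_p = {}, {}
    for roi in rois:
        z = np.column_stack([f1.xs(roi, level="roi")["z"].to_numpy(),
                             f2.xs(roi, level="roi")["z"].to_numpy()])
        p = np.column_stack([f1.xs(roi, level="roi")["p_fdr"].to_numpy(),
                             f2.xs(roi, level="roi")["p_fdr"].to_numpy()])
        icc_z[roi] = icc(z, model=icc_model) if np.isfinite(z).all() else np.nan
        icc_p[roi] = icc(p, model=icc_model) if np.isfinite(p).all() else np.nan

    wb_z = wb_p = float("nan")
    if est.whole_brain_col in f1.index.get_level_values("roi"):
        z1 = f1.xs(est.whole_brain_col, level="roi")
        z2 = f2.xs(est.whole_brain_col, level="roi")
        zmat = np.column_stack([z1["z"], z2["z"]])
        pmat = np.column_stack([z1["p_raw"], z2["p_raw"]])
        if np.isfinite(zmat).all():
            wb_z = icc(zmat, model=icc_model)
        if np.isfinite(pmat).all():
            wb_p = icc(pmat, model=icc_model)

    tracts1 = f1[~f1["standalone"]].groupby(level="subject", sort=False)["abnormal"].any()
    tracts2 = f2[~f2["standalone"]].groupby(level="subject", sort=False)["abnormal"].any()
    classes = pd.DataFrame({"t1": tracts1, "t2": tracts2}).loc[ids1]
    classes = classes.map(lambda b: "abnormal" if b else "normal")
    agreement = pd.crosstab(classes["t1"], classes["t2"]).reindex(
        index=["abnormal", "normal"], columns=["abnormal", "normal"], fill_value=0)
    return LongitudinalReliability(
        icc_z=pd.Series(icc_z), icc_pfdr=pd.Series(icc_p),
        whole_brain_icc_z=wb_z, whole_brain_icc_p=wb_p,
        classifications=classes, agreement=agreement, icc_model=icc_model,
    )
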