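"""Diagnostic plot: patient tract FA over the control distributions."""
from __future__ import annotations

import numpy as np

from .cohort import CohortFATable
from .normative import DiagnosticResult

__all__ = ["plot_diagnosis"]


def plot_diagnosis(result: DiagnosticResult, controls: CohortFATable, ax=None):
    """Box plots of control FA per tract with the patient overlaid.

    Tracts with FDR-significant lower FA are drawn in red; significant
    high-FA outliers in orange; the whole-brain skeleton value (stand-alone
    test) is appended after a separator.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.0 + 0.8 * len(result.table), 4.0))
    ctrl = controls.values_frame
    names = [r for r in result.table.index if r in ctrl.columns]
    data = [ctrl[r].dropna().to_numpy() for r in names]
    positions = list(range(1, len(names) + 1))
    labels = list(names)
    if result.whole_brain is not None and "WSKL" in ctrl.columns:
        data.append(ctrl["WSKL"].dropna().to_numpy())
        positions.append(len(names) + 2)  # gap marks the stand-alone test
        labels.append("WSKL")
    ax.boxplot(data, positions=positions, widths=0.6)
    for pos, roi in zip(positions, names):
        row = result.table.loc[roi]
        if bool(row.get("missing", False)) or not np.isfinite(row["x"]):
            continue
        color = "red" if row["abnormal"] else ("orange" if row.get("high_fa") else "black")
        ax.plot(pos, row["x"], "o", color=color, zorder=3)
    if result.whole_brain is not None and "WSKL" in ctrl.columns:
        wb = result.whole_brain
        color = "red" if wb["abnormal"] else ("orange" if wb.get("high_fa") else "black")
        ax.plot(positions[-1], wb["x"], "o", color=color, zorder=3)
    ax.set_xticks(positions)
    ax.set_xticklabels(labels, rotation=45, ha="right")
    ax.set_ylabel("mean FA" if result.scale == "raw" else f"mean FA ({result.scale})")
    ax.set_title(f"{result.subject_id}: {result.classification} "
                 f"(alpha={result.alpha}, n={result.n_controls} controls)")
    return ax
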