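"""On-disk formats: NIfTI volumes, TSV tables, JSON/CSV reports."""
from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Literal, Mapping

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .cohort import SubjectRecord
from .normative import DiagnosticResult
from .volumes import BinaryMask, FAVolume, LabelVolume, VoxelGrid

__all__ = [
    "load_volume",
    "save_volume",
    "load_label_names",
    "save_label_names",
    "load_participants",
    "write_report",
    "read_report",
]


def load_volume(path: str | Path, expected: Literal["fa", "mask", "labels"],
                rebinarize_threshold: float | None = None,
                name_map: Mapping[str, Iterable[int]] | None = None):
    """Read a NIfTI volume as the requested datatype class.

    ``expected='mask'`` rejects non-{0,1} data unless ``rebinarize_threshold``
    is given (values strictly above the threshold become 1 - the default
    policy after linear resampling of a drawn lesion mask is a 0.5 cut).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-d volume, got shape {data.shape}")
    grid = VoxelGrid(data.shape, img.affine)
    if expected == "fa":
        return FAVolume(data, grid)
    if expected == "mask":
        return BinaryMask(data, grid, rebinarize_threshold=rebinarize_threshold)
    if expected == "labels":
        nm = {k: frozenset(int(i) for i in v) for k, v in (name_map or {}).items()}
        return LabelVolume(data, grid, name_map=nm or None)
    raise ValueError(f"unknown expected datatype {expected!r}")


def save_volume(volume, path: str | Path) -> Path:
    path = Path(path)
    data = volume.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, volume.grid.affine), str(path))
    return path


def load_label_names(path: str | Path) -> dict[str, frozenset[int]]:
    """Label-name table: TSV with columns ``name`` and comma-separated ``labels``."""
    df = pd.read_csv(path, sep="\t")
    for col in ("name", "labels"):
        if col not in df.columns:
            raise ValueError(f"{path}: label table needs a {col!r} column")
    out: dict[str, frozenset[int]] = {}
    for _, row in df.iterrows():
        name = str(row["name"])
        if name in out:
            raise ValueError(f"{path}: duplicate label-group name {name!r}")
        out[name] = frozenset(int(tok) for tok in str(row["labels"]).split(","))
    return out


def save_label_names(name_map: Mapping[str, Iterable[int]], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"name": list(name_map),
         "labels": [",".join(str(i) for i in sorted(v)) for v in name_map.values()]}
    ).to_csv(path, sep="\t", index=False)
    return path


def load_participants(path: str | Path) -> list[SubjectRecord]:
    """BIDS-like participants TSV: subject_id, group, age [, timepoint, lesion_mask]."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    required = {"subject_id", "group", "age"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: participants table missing columns {sorted(missing)}")
    ages = pd.to_numeric(df["age"], errors="coerce")
    if ages.isna().any():
        bad = df.loc[ages.isna(), "subject_id"].tolist()
        raise ValueError(f"{path}: non-numeric age for subjects {bad}")
    if "timepoint" not in df.columns:
        df = df.assign(timepoint="single")
    key = list(zip(df["subject_id"], df["timepoint"]))
    dupes = sorted({k[0] for k in key if key.count(k) > 1})
    if dupes:
        raise ValueError(f"{path}: duplicate (subject_id, timepoint) for {dupes}")
    records = []
    for i, row in df.iterrows():
        records.append(SubjectRecord(
            subject_id=str(row["subject_id"]), group=str(row["group"]),
            age=float(ages.iloc[i]), timepoint=str(row["timepoint"]),
            lesion_mask=(str(row["lesion_mask"])
                         if "lesion_mask" in df.columns and pd.notna(row["lesion_mask"])
                         else None),
        ))
    return records


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def _result_payload(result, seed=None, config: dict | None = None) -> dict:
    if not hasattr(result, "to_dict"):
        raise TypeError(f"cannot serialize report of type {type(result).__name__}")
    return {
        "pipeline_version": __version__,
        "seed": seed,
        "config": config or {},
        "report_type": type(result).__name__,
        "result": result.to_dict(),
    }


def write_report(result, path: str | Path, format: Literal["json", "csv"] = "json",
                 seed=None, config: dict | None = None) -> Path:
    """Write a diagnostic or evaluation report.

    JSON embeds the pipeline version, seed and config snapshot and
    round-trips all numeric fields exactly. The CSV form of a
    :class:`DiagnosticResult` has one row per tract ROI plus one whole-brain
    row flagged ``standalone``.
    """
    path = Path(path)
    if isinstance(result, DiagnosticResult) and result.table.empty:
        raise ValueError("no ROIs in diagnostic result; nothing to report")
    if format == "json":
        path.write_text(json.dumps(_result_payload(result, seed, config), indent=2))
        return path
    if format == "csv":
        if not isinstance(result, DiagnosticResult):
            raise TypeError("CSV reports are supported for DiagnosticResult only")
        tbl = result.table.copy()
        tbl["standalone"] = False
        if result.whole_brain is not None:
            wb = result.whole_brain
            tbl.loc["WSKL_standalone" if "WSKL" in tbl.index else "WSKL"] = {
                "x": wb["x"], "z": wb["z"], "p_raw": wb["p_raw"], "p_fdr": np.nan,
                "abnormal": wb["abnormal"], "high_fa": wb["high_fa"],
                "transform": "none", "extreme_rank": False, "missing": False,
                "standalone": True,
            }
        tbl.rename_axis("roi").reset_index().to_csv(path, index=False)
        return path
    raise ValueError(f"unknown report format {format!r}")


def read_report(path: str | Path) -> tuple[object, dict]:
    """Read a JSON report back; returns ``(result, metadata)``.

    Only :class:`DiagnosticResult` reports are reconstructed as objects;
    evaluation reports come back as their dict payload.
    """
    payload = json.loads(Path(path).read_text())
    meta = {k: payload[k] for k in ("pipeline_version", "seed", "config", "report_type")}
    if payload["report_type"] == "DiagnosticResult":
        return DiagnosticResult.from_dict(payload["result"]), meta
    return payload["result"], meta
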