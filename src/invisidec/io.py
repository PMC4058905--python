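"""Reading and writing the standard formats the pipeline touches.

NIfTI-1 for 4-D voxel data and 3-D integer label volumes, tab-separated
tables for events/behavior/labels/results, JSON for reports.  Volumes are
0-based, onsets are seconds from the first volume, and events occupy the
half-open interval [onset, onset + duration).  Bilateral ROIs are assembled
by merging left/right labels that share a region name.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .design import CATEGORIES, METHODS, TrialSchedule, TrialSpec
from .synthetic_data import RoiAtlasSpec, RoiDataset, RunData

EVENTS_REQUIRED = ("onset", "duration", "method", "category", "exemplar", "color")
EVENTS_OPTIONAL = ("guess", "correct", "breakthrough", "seen")
HEMISPHERES = ("L", "R", "none")


# ---------------------------------------------------------------------------
# Events tables
# ---------------------------------------------------------------------------

def normalize_events(events: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize an events table in place conventions.

    Methods are upper-cased to {VIS, CFS, CFF}, categories lower-cased to
    {face, tool}; unknown values raise with the offending field named.
    """
    missing = [c for c in EVENTS_REQUIRED if c not in events.columns]
    if missing:
        raise ValueError(f"events table is missing required columns: {missing}")
    out = events.copy()
    out["method"] = out["method"].astype(str).str.upper()
    bad = sorted(set(out["method"]) - set(METHODS))
    if bad:
        raise ValueError(f"unknown values in column 'method': {bad}")
    out["category"] = out["category"].astype(str).str.lower()
    bad = sorted(set(out["category"]) - set(CATEGORIES))
    if bad:
        raise ValueError(f"unknown values in column 'category': {bad}")
    if "guess" in out.columns:
        out["guess"] = out["guess"].astype(str).str.lower()
    for col in ("breakthrough", "seen", "correct"):
        if col in out.columns:
            out[col] = out[col].map(_parse_bool)
    out["exemplar"] = out["exemplar"].astype(int)
    return out


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("1", "true", "t", "yes"):
        return True
    if s in ("0", "false", "f", "no"):
        return False
    raise ValueError(f"cannot interpret {v!r} as a boolean")


def read_events(path: str | Path) -> pd.DataFrame:
    return normalize_events(pd.read_csv(path, sep="\t"))


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Label tables and bilateral ROI assembly
# ---------------------------------------------------------------------------

def read_label_table(path: str | Path) -> pd.DataFrame:
    """Label table TSV with columns label, name, hemisphere."""
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in ("label", "name", "hemisphere") if c not in table.columns]
    if missing:
        raise ValueError(f"label table is missing columns: {missing}")
    if table["label"].duplicated().any():
        dupes = sorted(table.loc[table["label"].duplicated(), "label"])
        raise ValueError(f"duplicate labels in label table: {dupes}")
    bad = sorted(set(table["hemisphere"].astype(str)) - set(HEMISPHERES))
    if bad:
        raise ValueError(f"unknown hemisphere values: {bad} (expected {HEMISPHERES})")
    return table


def write_label_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def combine_hemispheres(table: pd.DataFrame) -> dict[str, list[int]]:
    """Merge L/R labels sharing a region name into bilateral ROIs.

    Returns region name -> list of integer labels.  Labels without a
    hemisphere pair (hemisphere == "none") pass through as their own ROI.
    A region name appearing twice within one hemisphere is an error.
    """
    dupes = table.duplicated(subset=["name", "hemisphere"], keep=False)
    if dupes.any():
        offenders = table.loc[dupes, ["name", "hemisphere"]].drop_duplicates()
        pairs = ", ".join(f"({n}, {h})" for n, h in offenders.itertuples(index=False))
        raise ValueError(f"duplicate region name within one hemisphere: {pairs}")
    rois: dict[str, list[int]] = {}
    for row in table.itertuples(index=False):
        rois.setdefault(str(row.name), []).append(int(row.label))
    return rois


# ---------------------------------------------------------------------------
# NIfTI round trip (timeseries mode)
# ---------------------------------------------------------------------------

def write_nifti_run(run: RunData, atlas: RoiAtlasSpec, out_dir: str | Path, prefix: str) -> dict[str, Path]:
    """Write one timeseries run as BOLD + label volume + label table + events.

    Voxels are laid out along the first axis, grouped by ROI; each ROI is
    split into a left and a right label so bilateral reassembly is
    exercised on read.
    """
    if run.mode != "timeseries":
        raise ValueError("NIfTI export is defined for timeseries runs")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    total_vox = sum(atlas.n_voxels(r) for r in atlas.roi_names)
    n_vol = run.schedule.n_volumes
    bold = np.zeros((total_vox, 1, 1, n_vol))
    labels = np.zeros((total_vox, 1, 1), dtype=np.int16)
    rows = []
    offset = 0
    next_label = 1
    for roi in atlas.roi_names:
        n = atlas.n_voxels(roi)
        series = run.data[roi]  # (T, V)
        bold[offset : offset + n, 0, 0, :] = series.T
        half = n // 2
        labels[offset : offset + half, 0, 0] = next_label
        labels[offset + half : offset + n, 0, 0] = next_label + 1
        rows.append({"label": next_label, "name": roi, "hemisphere": "L"})
        rows.append({"label": next_label + 1, "name": roi, "hemisphere": "R"})
        next_label += 2
        offset += n
    affine = np.eye(4)
    paths = {
        "bold": out_dir / f"{prefix}_bold.nii",
        "labels": out_dir / f"{prefix}_labels.nii",
        "label_table": out_dir / f"{prefix}_labels.tsv",
        "events": out_dir / f"{prefix}_events.tsv",
    }
    nib.save(nib.Nifti1Image(bold, affine), paths["bold"])
    nib.save(nib.Nifti1Image(labels, affine), paths["labels"])
    write_label_table(pd.DataFrame(rows), paths["label_table"])
    write_events(run.events, paths["events"])
    return paths


def read_nifti_run(
    bold_path: str | Path,
    labels_path: str | Path,
    label_table_path: str | Path,
    events_path: str | Path,
    index: int = 0,
    tr_seconds: float = 2.0,
) -> RunData:
    """Assemble a timeseries RunData from NIfTI volumes, labels and events.

    Per-ROI series are extracted by bilateral label masks; grid mismatch
    between data and labels, missing events columns, and labels absent from
    the label table are explicit errors.
    """
    bold_img = nib.load(str(bold_path))
    label_img = nib.load(str(labels_path))
    bold = np.asarray(bold_img.dataobj)
    label_vol = np.asarray(label_img.dataobj).astype(int)
    if bold.shape[:3] != label_vol.shape:
        raise ValueError(
            f"volume grid {bold.shape[:3]} does not match label grid {label_vol.shape}"
        )
    table = read_label_table(label_table_path)
    known = set(table["label"].astype(int))
    present = set(np.unique(label_vol)) - {0}
    unknown = sorted(present - known)
    if unknown:
        raise ValueError(f"labels present in the volume but absent from the label table: {unknown}")
    events = read_events(events_path)

    rois = combine_hemispheres(table)
    data: dict[str, np.ndarray] = {}
    voxels: dict[str, int] = {}
    for roi, labels in rois.items():
        mask = np.isin(label_vol, labels)
        if not mask.any():
            continue
        data[roi] = bold[mask].T  # (T, V)
        voxels[roi] = int(mask.sum())
    atlas = RoiAtlasSpec(roi_names=tuple(data.keys()), voxels_per_roi=voxels)
    schedule = schedule_from_events(events, tr_seconds=tr_seconds, n_volumes=bold.shape[3])
    return RunData(index=index, schedule=schedule, events=events, data=data, mode="timeseries")


def schedule_from_events(
    events: pd.DataFrame, tr_seconds: float = 2.0, n_volumes: int = 242
) -> TrialSchedule:
    """Rebuild a TrialSchedule from an events table (ISIs from onset gaps)."""
    trials = [
        TrialSpec(
            category=row.category, exemplar=int(row.exemplar), color=row.color, method=row.method
        )
        for row in events.itertuples(index=False)
    ]
    onsets = events["onset"].to_numpy(dtype=float)
    durations = events["duration"].to_numpy(dtype=float)
    isis = np.empty(len(onsets))
    isis[:-1] = np.diff(onsets) - durations[:-1]
    isis[-1] = isis[-2] if len(isis) > 1 else 6.0
    total = n_volumes * tr_seconds
    isis[-1] = min(isis[-1], total - onsets[-1] - durations[-1])
    return TrialSchedule(
        trials=trials, onsets=onsets, isis=isis, tr_seconds=tr_seconds, n_volumes=n_volumes
    )


# ---------------------------------------------------------------------------
# Trial-mode datasets as plain TSV directories
# ---------------------------------------------------------------------------

def write_trial_dataset(dataset: RoiDataset, out_dir: str | Path) -> Path:
    """Write a trial-mode subject as per-ROI pattern TSVs plus events TSVs.

    Plain-text float repr round-trips bit-exactly in Python 3.
    """
    out_dir = Path(out_dir) / dataset.subject
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {
        "subject": dataset.subject,
        "roi_names": list(dataset.atlas.roi_names),
        "voxels_per_roi": {r: dataset.atlas.n_voxels(r) for r in dataset.atlas.roi_names},
        "n_runs": dataset.n_runs,
        "mode": "trial",
    }
    (out_dir / "dataset.json").write_text(json.dumps(meta, indent=2))
    for run in dataset.runs:
        if run.mode != "trial":
            raise ValueError("write_trial_dataset expects trial-mode runs")
        prefix = f"run-{run.index:02d}"
        write_events(run.events, out_dir / f"{prefix}_events.tsv")
        for roi, patterns in run.data.items():
            pd.DataFrame(patterns).to_csv(
                out_dir / f"{prefix}_roi-{roi}_patterns.tsv",
                sep="\t",
                index=False,
                float_format="%.17g",  # bit-exact text round trip
            )
    return out_dir


def read_trial_dataset(subject_dir: str | Path, tr_seconds: float = 2.0) -> RoiDataset:
    """Read a subject directory written by :func:`write_trial_dataset`."""
    subject_dir = Path(subject_dir)
    meta = json.loads((subject_dir / "dataset.json").read_text())
    atlas = RoiAtlasSpec(
        roi_names=tuple(meta["roi_names"]),
        voxels_per_roi={k: int(v) for k, v in meta["voxels_per_roi"].items()},
    )
    runs = []
    for i in range(int(meta["n_runs"])):
        prefix = f"run-{i:02d}"
        events = read_events(subject_dir / f"{prefix}_events.tsv")
        data = {
            roi: pd.read_csv(
                subject_dir / f"{prefix}_roi-{roi}_patterns.tsv",
                sep="\t",
                float_precision="round_trip",
            ).to_numpy()
            for roi in atlas.roi_names
        }
        schedule = schedule_from_events(events, tr_seconds=tr_seconds)
        runs.append(RunData(index=i, schedule=schedule, events=events, data=data, mode="trial"))
    return RoiDataset(subject=meta["subject"], atlas=atlas, runs=runs)


# ---------------------------------------------------------------------------
# Results and reports
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_report(report: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))
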