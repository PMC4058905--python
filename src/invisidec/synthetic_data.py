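"""Synthetic multi-subject, ROI-structured multivoxel datasets.

Plants method-dependent category information into per-ROI voxel patterns so
the full decoding chain (QC -> cross-exemplar leave-one-run-out
classification -> group inference) can be exercised and validated without
real scans.  Each (ROI, method) pair gets a unit category-coding axis; an
overlap parameter rho controls how much of that axis is shared across
methods, which is what cross-method decoding can exploit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import design
from .design import METHODS, INVISIBLE_METHODS, CATEGORIES, TrialSchedule

# Twelve bilateral ROI abbreviations with full names and surface areas (cm^2)
# used to set default voxel counts (proportional, ~25-200 voxels).
ROI_TABLE: tuple[tuple[str, str, float], ...] = (
    ("IOGS", "Inferior occipital gyrus and sulcus", 23.96),
    ("MFG", "Middle frontal gyrus", 64.96),
    ("MOG", "Middle occipital gyrus", 33.69),
    ("FG", "Fusiform gyrus", 27.08),
    ("LG", "Lingual gyrus", 42.04),
    ("OP", "Occipital pole", 38.05),
    ("CTPS", "Posterior transverse collateral sulcus", 8.36),
    ("IPS", "Intraparietal sulcus", 55.58),
    ("MLOS", "Middle occipital and lunate sulci", 17.84),
    ("AOS", "Anterior occipital sulcus", 13.24),
    ("LOTS", "Lateral occipitotemporal sulcus", 17.66),
    ("SPCS", "Precentral sulcus, superior part", 24.32),
)

ROI_FULL_NAMES: dict[str, str] = {abbr: full for abbr, full, _ in ROI_TABLE}

# Scenario presets: which (ROI, method) cells carry category signal, and
# where the coding axis is shared across methods.
CFS_PLANTED_ROIS: frozenset[str] = frozenset({"MOG", "LG", "MLOS"})
CFF_PLANTED_ROIS: frozenset[str] = frozenset({"LG", "FG", "SPCS"})
HIGH_RHO_ROIS: frozenset[str] = frozenset({"IOGS", "MOG", "LG", "OP", "MLOS", "AOS"})
SCENARIOS: tuple[str, ...] = ("paper_like", "null", "full_transfer", "custom")


@dataclass(frozen=True)
class RoiAtlasSpec:
    """Named ROIs and their voxel counts."""

    roi_names: tuple[str, ...]
    voxels_per_roi: Mapping[str, int]

    def __post_init__(self) -> None:
        if len(set(self.roi_names)) != len(self.roi_names):
            raise ValueError("ROI names must be unique")
        for name in self.roi_names:
            n = self.voxels_per_roi.get(name, 0)
            if n < 2:
                raise ValueError(f"ROI {name!r} must have >= 2 voxels, got {n}")

    @classmethod
    def default(cls, scale: float = 3.0) -> "RoiAtlasSpec":
        """The 12-ROI atlas with voxel counts proportional to surface area."""
        names = tuple(abbr for abbr, _, _ in ROI_TABLE)
        voxels = {abbr: max(2, round(scale * size)) for abbr, _, size in ROI_TABLE}
        return cls(roi_names=names, voxels_per_roi=voxels)

    def n_voxels(self, roi: str) -> int:
        return int(self.voxels_per_roi[roi])


@dataclass
class CodingAxes:
    """Per-(ROI, method) category coding axes with cross-method overlap.

    ``axes[(roi, m)]`` is a unit vector w = rho*w_shared + sqrt(1-rho^2)*w_m
    with w_m orthogonal to w_shared; ``amplitudes[(roi, m)]`` scales the
    face-vs-tool signal along it.
    """

    atlas: RoiAtlasSpec
    axes: dict[tuple[str, str], np.ndarray]
    amplitudes: dict[tuple[str, str], float]
    rho: dict[str, float]
    shared: dict[str, np.ndarray]
    scenario: str = "custom"

    def axis(self, roi: str, method: str) -> np.ndarray:
        return self.axes[(roi, method)]

    def amplitude(self, roi: str, method: str) -> float:
        return self.amplitudes[(roi, method)]


def _unit(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.standard_normal(n)
    return v / np.linalg.norm(v)


def _unit_orthogonal_to(rng: np.random.Generator, basis: Sequence[np.ndarray], n: int) -> np.ndarray:
    for _ in range(50):
        v = rng.standard_normal(n)
        for b in basis:
            v = v - np.dot(v, b) * b
        norm = np.linalg.norm(v)
        if norm > 1e-8:
            return v / norm
    raise RuntimeError("could not draw a vector orthogonal to the basis")


def sample_coding_axes(
    atlas: RoiAtlasSpec | None = None,
    scenario: str = "paper_like",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    vis_amplitude: float = 1.2,
    invisible_amplitude: float = 1.0,
    rho_high: float = 0.9,
    rho_low: float = 0.1,
    amplitudes: Mapping[tuple[str, str], float] | None = None,
    rho: Mapping[str, float] | None = None,
) -> CodingAxes:
    """Draw coding axes for a scenario.

    Scenarios
    ---------
    ``paper_like``
        Visible signal in all ROIs; CFS signal only in {MOG, LG, MLOS};
        CFF signal only in {LG, FG, SPCS}; axis overlap rho high only in
        posterior-occipital ROIs.
    ``null``
        All amplitudes zero (no category information anywhere).
    ``full_transfer``
        rho = 1 everywhere and signal in every (ROI, method) cell, so every
        cross-method regime transfers.
    ``custom``
        Caller supplies ``amplitudes`` and ``rho`` mappings.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    if atlas is None:
        atlas = RoiAtlasSpec.default()
    if rng is None:
        rng = np.random.default_rng(seed)

    amp: dict[tuple[str, str], float] = {}
    rho_map: dict[str, float] = {}
    for roi in atlas.roi_names:
        if scenario == "paper_like":
            amp[(roi, "VIS")] = vis_amplitude
            amp[(roi, "CFS")] = invisible_amplitude if roi in CFS_PLANTED_ROIS else 0.0
            amp[(roi, "CFF")] = invisible_amplitude if roi in CFF_PLANTED_ROIS else 0.0
            rho_map[roi] = rho_high if roi in HIGH_RHO_ROIS else rho_low
        elif scenario == "null":
            for m in METHODS:
                amp[(roi, m)] = 0.0
            rho_map[roi] = rho_low
        elif scenario == "full_transfer":
            for m in METHODS:
                amp[(roi, m)] = invisible_amplitude
            rho_map[roi] = 1.0
        else:  # custom
            if amplitudes is None or rho is None:
                raise ValueError("scenario='custom' requires amplitudes and rho mappings")
            for m in METHODS:
                amp[(roi, m)] = float(amplitudes[(roi, m)])
            rho_map[roi] = float(rho[roi])
    for r, value in rho_map.items():
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"rho for ROI {r!r} must lie in [0, 1], got {value}")
    if any(a < 0 for a in amp.values()):
        raise ValueError("amplitudes must be non-negative")

    axes: dict[tuple[str, str], np.ndarray] = {}
    shared: dict[str, np.ndarray] = {}
    for roi in atlas.roi_names:
        n = atlas.n_voxels(roi)
        w_shared = _unit(rng, n)
        shared[roi] = w_shared
        r = rho_map[roi]
        for m in METHODS:
            w_unique = _unit_orthogonal_to(rng, [w_shared], n)
            axes[(roi, m)] = r * w_shared + math.sqrt(max(0.0, 1.0 - r * r)) * w_unique
    return CodingAxes(
        atlas=atlas, axes=axes, amplitudes=amp, rho=rho_map, shared=shared, scenario=scenario
    )


def expected_significance(axes: CodingAxes, rho_threshold: float = 0.5) -> dict[str, frozenset[str]]:
    """Planted ground truth per regime, derived from the axes themselves.

    A within-method cell is decodable where its amplitude is positive; a
    cross-method cell where both methods carry signal and their axes overlap
    (rho above *rho_threshold*).
    """
    rois = axes.atlas.roi_names
    truth: dict[str, frozenset[str]] = {}
    for m in METHODS:
        truth[f"within:{m}"] = frozenset(r for r in rois if axes.amplitude(r, m) > 0)
    for m1 in METHODS:
        for m2 in METHODS:
            if m1 == m2:
                continue
            truth[f"cross:{m1}-{m2}"] = frozenset(
                r
                for r in rois
                if axes.amplitude(r, m1) > 0
                and axes.amplitude(r, m2) > 0
                and axes.rho[r] >= rho_threshold
            )
    return truth


# ---------------------------------------------------------------------------
# Behavior
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BehaviorRates:
    """Bernoulli rates governing simulated button-box behavior."""

    invisible_accuracy: float = 0.5
    breakthrough_cfs: float = 0.031
    breakthrough_cff: float = 0.043
    visible_accuracy: float = 0.994
    visible_seen: float = 0.962

    def __post_init__(self) -> None:
        for name in (
            "invisible_accuracy",
            "breakthrough_cfs",
            "breakthrough_cff",
            "visible_accuracy",
            "visible_seen",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def breakthrough(self, method: str) -> float:
        return {"CFS": self.breakthrough_cfs, "CFF": self.breakthrough_cff}[method]


def simulate_behavior(
    schedule: TrialSchedule,
    rates: BehaviorRates | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-trial guesses, breakthrough flags and seen reports.

    Invisible trials are guessed at chance (by default) with rare
    breakthrough; visible trials are near ceiling and almost always reported
    as clearly seen.  All draws are independent Bernoulli.
    """
    if rates is None:
        rates = BehaviorRates()
    if rng is None:
        rng = np.random.default_rng(seed)
    rows = []
    for i, trial in enumerate(schedule.trials):
        if trial.method == "VIS":
            correct = bool(rng.random() < rates.visible_accuracy)
            seen = bool(rng.random() < rates.visible_seen)
            breakthrough = False
        else:
            correct = bool(rng.random() < rates.invisible_accuracy)
            breakthrough = bool(rng.random() < rates.breakthrough(trial.method))
            seen = breakthrough
        other = CATEGORIES[1 - CATEGORIES.index(trial.category)]
        rows.append(
            {
                "trial": i,
                "guess": trial.category if correct else other,
                "correct": correct,
                "breakthrough": breakthrough,
                "seen": seen,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Voxel data
# ---------------------------------------------------------------------------

def double_gamma_hrf(
    t: np.ndarray | float,
    peak: float = 5.0,
    undershoot: float = 15.0,
    ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, unit peak amplitude.

    Gamma shapes are chosen so the positive lobe peaks at *peak* seconds and
    the undershoot at *undershoot* seconds (scale 1).
    """
    t = np.asarray(t, dtype=float)
    pos = stats.gamma.pdf(t, peak + 1.0)
    neg = stats.gamma.pdf(t, undershoot + 1.0)
    h = pos - ratio * neg
    grid = np.linspace(0.0, undershoot + 20.0, 2000)
    scale = np.max(stats.gamma.pdf(grid, peak + 1.0) - ratio * stats.gamma.pdf(grid, undershoot + 1.0))
    return h / scale


@dataclass
class RunData:
    """One run of one subject: schedule, events+behavior, per-ROI voxel data."""

    index: int
    schedule: TrialSchedule
    events: pd.DataFrame
    data: dict[str, np.ndarray]
    mode: str  # "trial" (n_trials x V) or "timeseries" (n_volumes x V)

    def __post_init__(self) -> None:
        if self.mode not in ("trial", "timeseries"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for roi, arr in self.data.items():
            expected = self.schedule.n_trials if self.mode == "trial" else self.schedule.n_volumes
            if arr.shape[0] != expected:
                raise ValueError(
                    f"ROI {roi!r}: data has {arr.shape[0]} rows, expected {expected} for mode {self.mode!r}"
                )


@dataclass
class RoiDataset:
    """All runs of one subject, grouped by ROI, plus behavioral records."""

    subject: str
    atlas: RoiAtlasSpec
    runs: list[RunData]

    @property
    def n_runs(self) -> int:
        return len(self.runs)


def _category_sign(category: str) -> float:
    return 1.0 if category == "face" else -1.0


def simulate_subject(
    subject: str,
    schedules: Sequence[TrialSchedule],
    axes: CodingAxes,
    noise_sd: float = 1.0,
    mode: str = "trial",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    exemplar_sd: float = 0.3,
    color_amp: float = 0.5,
    baseline: float = 0.0,
    ar_coef: float = 0.3,
    rates: BehaviorRates | None = None,
) -> RoiDataset:
    """Simulate one subject's runs given schedules and planted coding axes.

    Trial mode produces one pattern row per trial:
    ``baseline + s_cat * a * w + exemplar offset + color nuisance + noise``
    with s_face = +1, s_tool = -1.  Exemplar offsets are drawn once per
    subject and reused across runs, so splits by exemplar set test
    generalization beyond exemplar identity; the color nuisance direction is
    orthogonal to every category axis by construction.  Timeseries mode
    convolves the same trial signals with a double-gamma HRF sampled at the
    TR and adds AR(1) noise with stationary standard deviation *noise_sd*.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    if mode not in ("trial", "timeseries"):
        raise ValueError(f"unknown mode {mode!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    atlas = axes.atlas

    # Fixed per-subject structure, shared across runs.
    exemplar_offsets: dict[str, dict[tuple[str, int], np.ndarray]] = {}
    color_dirs: dict[str, np.ndarray] = {}
    for roi in atlas.roi_names:
        n = atlas.n_voxels(roi)
        exemplar_offsets[roi] = {
            (cat, ex): exemplar_sd * _unit(rng, n)
            for cat in CATEGORIES
            for ex in design.EXEMPLAR_IDS
        }
        basis = _gram_schmidt([axes.shared[roi]] + [axes.axis(roi, m) for m in METHODS])
        if len(basis) < n:
            color_dirs[roi] = _unit_orthogonal_to(rng, basis, n)
        else:
            # Tiny ROI: no direction orthogonal to every category axis is
            # left, so the color nuisance vanishes there.
            color_dirs[roi] = np.zeros(n)

    runs: list[RunData] = []
    for run_index, schedule in enumerate(schedules):
        behavior = simulate_behavior(schedule, rates=rates, rng=rng)
        events = pd.concat(
            [schedule.to_events(), behavior.drop(columns="trial")], axis=1
        )
        data: dict[str, np.ndarray] = {}
        for roi in atlas.roi_names:
            n = atlas.n_voxels(roi)
            signal = np.zeros((schedule.n_trials, n))
            for i, trial in enumerate(schedule.trials):
                s = _category_sign(trial.category)
                s_color = 1.0 if trial.color == "red" else -1.0
                signal[i] = (
                    s * axes.amplitude(roi, trial.method) * axes.axis(roi, trial.method)
                    + exemplar_offsets[roi][(trial.category, trial.exemplar)]
                    + s_color * color_amp * color_dirs[roi]
                )
            if mode == "trial":
                data[roi] = baseline + signal + rng.normal(0.0, noise_sd, signal.shape)
            else:
                t_vol = np.arange(schedule.n_volumes) * schedule.tr_seconds
                resp = np.zeros((schedule.n_volumes, schedule.n_trials))
                for i, onset in enumerate(schedule.onsets):
                    dt = t_vol - onset
                    m = dt > 0
                    resp[m, i] = double_gamma_hrf(dt[m])
                series = baseline + resp @ signal
                series += _ar1_noise(rng, series.shape, noise_sd, ar_coef)
                data[roi] = series
        runs.append(RunData(index=run_index, schedule=schedule, events=events, data=data, mode=mode))
    return RoiDataset(subject=subject, atlas=atlas, runs=runs)


def _gram_schmidt(vectors: Sequence[np.ndarray]) -> list[np.ndarray]:
    basis: list[np.ndarray] = []
    for v in vectors:
        w = v.astype(float).copy()
        for b in basis:
            w -= np.dot(w, b) * b
        norm = np.linalg.norm(w)
        if norm > 1e-10:
            basis.append(w / norm)
    return basis


def _ar1_noise(
    rng: np.random.Generator, shape: tuple[int, int], sd: float, ar_coef: float
) -> np.ndarray:
    """AR(1) noise per column with stationary standard deviation *sd*."""
    t, v = shape
    innov_sd = sd * math.sqrt(max(0.0, 1.0 - ar_coef**2))
    out = np.empty(shape)
    out[0] = rng.normal(0.0, sd, v)
    eps = rng.normal(0.0, innov_sd, (t - 1, v)) if t > 1 else np.empty((0, v))
    for i in range(1, t):
        out[i] = ar_coef * out[i - 1] + eps[i - 1]
    return out


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """Simulated multi-subject study: datasets, run manifest, planted axes."""

    datasets: list[RoiDataset]
    manifest: pd.DataFrame
    axes: CodingAxes


def subject_label(i: int) -> str:
    return f"sub-{i + 1:02d}"


def simulate_cohort(
    n_subjects: int = 17,
    n_runs: int = 8,
    scenario: str = "paper_like",
    seed: int | None = None,
    atlas: RoiAtlasSpec | None = None,
    mode: str = "trial",
    n_candidates: int = 1000,
    axes: CodingAxes | None = None,
    axes_kwargs: Mapping | None = None,
    **subject_kwargs,
) -> Cohort:
    """Simulate a full cohort (default 17 subjects x 8 runs).

    Every subject gets independently optimized run orders and an
    independent noise stream, all derived from one seed via spawned
    substreams, so the cohort is reproducible as a whole.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_subjects + 1)
    if axes is None:
        axes = sample_coding_axes(
            atlas=atlas,
            scenario=scenario,
            rng=np.random.default_rng(children[0]),
            **dict(axes_kwargs or {}),
        )
    datasets = []
    rows = []
    for i in range(n_subjects):
        rng = np.random.default_rng(children[i + 1])
        schedules = design.generate_subject_schedules(n_runs, n_candidates=n_candidates, rng=rng)
        dataset = simulate_subject(
            subject_label(i), schedules, axes, mode=mode, rng=rng, **subject_kwargs
        )
        datasets.append(dataset)
        for run in dataset.runs:
            rows.append(
                {
                    "subject": dataset.subject,
                    "run": run.index,
                    "n_trials": run.schedule.n_trials,
                    "n_volumes": run.schedule.n_volumes,
                }
            )
    return Cohort(datasets=datasets, manifest=pd.DataFrame(rows), axes=axes)
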