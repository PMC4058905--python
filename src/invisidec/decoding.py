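"""Cross-exemplar leave-one-run-out decoding of category from voxel patterns.

Trial patterns (for time series, the average of the volumes 4 s and 6 s
after onset) are averaged within run x method x category x exemplar-set
cells.  Within-method folds hold out one run and one exemplar set at a
time, so train and test never share a run or an exemplar; cross-method
folds train on one presentation method and test on a held-out run of
another.  A linear soft-margin SVM (C = 1) is trained per fold after
z-scoring features on training statistics only; confusion counts are pooled
over folds and summarized once as accuracy and d-prime (log-linear
corrected), with "face" as the signal class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri
from sklearn.svm import SVC

from .design import CATEGORIES, METHODS, EXEMPLAR_IDS

if TYPE_CHECKING:  # pragma: no cover
    from .qc import UsabilityMask
    from .synthetic_data import RoiDataset, RunData

SET_LABELS = ("A", "B")
SIGNAL_CATEGORY = "face"

DEFAULT_REGIMES = (
    "within:VIS",
    "within:CFS",
    "within:CFF",
    "cross:CFS-CFF",
    "cross:CFF-CFS",
    "cross:VIS-CFS",
    "cross:VIS-CFF",
    "cross:CFS-VIS",
    "cross:CFF-VIS",
)


def parse_regime(regime: str) -> tuple[str, str, str]:
    """Split a regime string into (kind, train_method, test_method)."""
    kind, _, rest = regime.partition(":")
    if kind == "within":
        if rest not in METHODS:
            raise ValueError(f"unknown method in regime {regime!r}")
        return "within", rest, rest
    if kind == "cross":
        m1, _, m2 = rest.partition("-")
        if m1 not in METHODS or m2 not in METHODS or m1 == m2:
            raise ValueError(f"invalid cross regime {regime!r}")
        return "cross", m1, m2
    raise ValueError(f"unknown regime kind in {regime!r}")


@dataclass(frozen=True)
class ExemplarSplit:
    """Disjoint exemplar-id sets A/B, balanced by category by construction.

    Exemplar ids are 1..4 *within* each category, so a split of ids splits
    both faces and tools the same way: each set holds 2 faces and 2 tools.
    """

    set_a: frozenset[int]
    set_b: frozenset[int]

    def __post_init__(self) -> None:
        if self.set_a & self.set_b:
            raise ValueError("exemplar sets must be disjoint")
        if self.set_a | self.set_b != set(EXEMPLAR_IDS):
            raise ValueError(f"exemplar sets must cover {EXEMPLAR_IDS}")
        if len(self.set_a) != 2:
            raise ValueError("each exemplar set must contain 2 ids per category")

    @classmethod
    def default(cls) -> "ExemplarSplit":
        return cls(frozenset({1, 2}), frozenset({3, 4}))

    @classmethod
    def random(cls, rng: np.random.Generator) -> "ExemplarSplit":
        ids = list(EXEMPLAR_IDS)
        rng.shuffle(ids)
        return cls(frozenset(ids[:2]), frozenset(ids[2:]))

    def label(self, exemplar: int) -> str:
        if exemplar in self.set_a:
            return "A"
        if exemplar in self.set_b:
            return "B"
        raise ValueError(f"exemplar {exemplar} not in either set")


# ---------------------------------------------------------------------------
# Pattern extraction and cell averaging
# ---------------------------------------------------------------------------

def extract_trial_pattern(
    series: np.ndarray,
    onset: float,
    tr: float = 2.0,
    offsets: Sequence[int] = (2, 3),
) -> np.ndarray:
    """Mean of the volumes *offsets* TRs (default 4 s and 6 s) after onset.

    Volume index is ``floor((onset + offset * tr) / tr)``.

    Raises
    ------
    ValueError
        If the onset is too close to the run end to cover the window
        (the caller should flag the trial unusable).
    """
    idx = [math.floor((onset + o * tr) / tr) for o in offsets]
    if max(idx) >= series.shape[0]:
        raise ValueError(
            f"onset {onset} s needs volume {max(idx)} but the series has only {series.shape[0]}"
        )
    return series[idx].mean(axis=0)


def trial_patterns(run: "RunData", tr: float | None = None) -> dict[str, np.ndarray]:
    """Per-ROI (n_trials x V) pattern matrices for one run."""
    if run.mode == "trial":
        return run.data
    tr = tr if tr is not None else run.schedule.tr_seconds
    out = {}
    for roi, series in run.data.items():
        out[roi] = np.stack(
            [extract_trial_pattern(series, onset, tr=tr) for onset in run.schedule.onsets]
        )
    return out


def average_patterns(patterns: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Unweighted mean pattern over the selected trial rows.

    Raises
    ------
    ValueError
        If no rows are selected (QC should have dropped the block).
    """
    rows = np.asarray(rows)
    if rows.dtype == bool:
        if not rows.any():
            raise ValueError("cannot average an empty cell")
        return patterns[rows].mean(axis=0)
    if len(rows) == 0:
        raise ValueError("cannot average an empty cell")
    return patterns[rows].mean(axis=0)


CellKey = tuple[int, str, str, str]  # (run, method, category, set label)


def make_cell_patterns(
    dataset: "RoiDataset", mask: "UsabilityMask", split: ExemplarSplit
) -> dict[str, dict[CellKey, np.ndarray]]:
    """Averaged cell patterns per ROI for every retained (run, method) block."""
    cells: dict[str, dict[CellKey, np.ndarray]] = {roi: {} for roi in dataset.atlas.roi_names}
    for run in dataset.runs:
        events = run.events
        methods = events["method"].to_numpy()
        cats = events["category"].to_numpy()
        set_labels = np.array([split.label(e) for e in events["exemplar"]])
        usable = mask.trial_usable[run.index]
        pats = trial_patterns(run)
        for m in METHODS:
            if not mask.retained.get((run.index, m), False):
                continue
            for cat in CATEGORIES:
                for lab in SET_LABELS:
                    sel = usable & (methods == m) & (cats == cat) & (set_labels == lab)
                    for roi in dataset.atlas.roi_names:
                        cells[roi][(run.index, m, cat, lab)] = average_patterns(pats[roi], sel)
    return cells


# ---------------------------------------------------------------------------
# Fold plans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fold:
    train: tuple[CellKey, ...]
    test: tuple[CellKey, ...]


@dataclass
class FoldPlan:
    regime: str
    folds: list[Fold]

    def __len__(self) -> int:
        return len(self.folds)


def make_folds_within(runs: Sequence[int], method: str) -> FoldPlan:
    """Cross-exemplar leave-one-run-out folds for one method.

    For each held-out run and each direction (train set A / test set B, and
    the swap), train on the training set's cells from all other runs and
    test on the opposite set's cells from the held-out run: 2 * |runs|
    folds in total.

    Raises
    ------
    ValueError
        With fewer than 2 retained runs.
    """
    runs = sorted(runs)
    if len(runs) < 2:
        raise ValueError(f"need >= 2 retained runs for within-method folds, got {len(runs)}")
    folds = []
    for held_out in runs:
        for train_set, test_set in (("A", "B"), ("B", "A")):
            train = tuple(
                (r, method, cat, train_set) for r in runs if r != held_out for cat in CATEGORIES
            )
            test = tuple((held_out, method, cat, test_set) for cat in CATEGORIES)
            folds.append(Fold(train=train, test=test))
    return FoldPlan(regime=f"within:{method}", folds=folds)


def make_folds_cross(
    method_train: str,
    method_test: str,
    runs_train: Sequence[int],
    runs_test: Sequence[int],
    cross_exemplar: bool = True,
) -> FoldPlan:
    """Cross-method folds: train on one method, test on a held-out run of another.

    With ``cross_exemplar=True`` (default) the exemplar-set constraint of the
    within-method analysis also applies, giving two set-directions per
    held-out run; otherwise both sets appear on both sides and there is one
    fold per held-out run.
    """
    if method_train == method_test:
        raise ValueError("cross-method folds need two distinct methods")
    runs_train = sorted(runs_train)
    runs_test = sorted(runs_test)
    folds = []
    for held_out in runs_test:
        train_runs = [r for r in runs_train if r != held_out]
        if not train_runs:
            continue
        directions = (("A", "B"), ("B", "A")) if cross_exemplar else ((None, None),)
        for train_set, test_set in directions:
            train_sets = (train_set,) if train_set else SET_LABELS
            test_sets = (test_set,) if test_set else SET_LABELS
            train = tuple(
                (r, method_train, cat, s)
                for r in train_runs
                for cat in CATEGORIES
                for s in train_sets
            )
            test = tuple(
                (held_out, method_test, cat, s) for cat in CATEGORIES for s in test_sets
            )
            folds.append(Fold(train=train, test=test))
    if not folds:
        raise ValueError("no cross-method folds could be formed from the retained runs")
    return FoldPlan(regime=f"cross:{method_train}-{method_test}", folds=folds)


def make_fold_plan(
    regime: str, mask: "UsabilityMask", cross_exemplar: bool = True
) -> FoldPlan:
    """Fold plan for a regime given a subject's QC retention."""
    kind, m1, m2 = parse_regime(regime)
    if kind == "within":
        return make_folds_within(mask.retained_runs(m1), m1)
    return make_folds_cross(
        m1, m2, mask.retained_runs(m1), mask.retained_runs(m2), cross_exemplar=cross_exemplar
    )


# ---------------------------------------------------------------------------
# Classifier, evaluation, d-prime
# ---------------------------------------------------------------------------

def train_linear_classifier(X: np.ndarray, y: np.ndarray) -> SVC:
    """Linear soft-margin SVM with the conventional default C = 1.

    Deterministic for a fixed input order; raises on a single-class
    training set.
    """
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    clf = SVC(kernel="linear", C=1.0)
    clf.fit(X, y)
    return clf


def dprime(h: int, m: int, fa: int, cr: int, correction: str = "log_linear") -> float:
    """Signal-detection sensitivity z(hit rate) - z(false-alarm rate).

    ``correction="log_linear"`` adds 0.5 to hits and false alarms and 1 to
    each trial count, keeping d-prime finite at perfect rates;
    ``correction="none"`` uses the raw rates (and may return +/-inf).
    """
    if h + m <= 0 or fa + cr <= 0:
        raise ValueError("both signal and noise test trials are required")
    if correction == "log_linear":
        hr = (h + 0.5) / (h + m + 1.0)
        far = (fa + 0.5) / (fa + cr + 1.0)
    elif correction == "none":
        hr = h / (h + m)
        far = fa / (fa + cr)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return float(ndtri(hr) - ndtri(far))


@dataclass
class DecodingResult:
    """Pooled confusion counts and scores for one (subject, ROI, regime)."""

    subject: str
    roi: str
    regime: str
    h: int
    m: int
    fa: int
    cr: int
    n_folds: int
    correction: str = "log_linear"

    @property
    def n_test(self) -> int:
        return self.h + self.m + self.fa + self.cr

    @property
    def accuracy(self) -> float:
        return (self.h + self.cr) / self.n_test if self.n_test else float("nan")

    @property
    def dprime(self) -> float:
        if self.h + self.m == 0 or self.fa + self.cr == 0:
            return float("nan")
        return dprime(self.h, self.m, self.fa, self.cr, correction=self.correction)


def _zscore_train_stats(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd < 1e-12] = 1.0
    return mu, sd


def evaluate(
    plan: FoldPlan,
    cells: Mapping[CellKey, np.ndarray],
    subject: str = "",
    roi: str = "",
    scale: bool = True,
    correction: str = "log_linear",
) -> DecodingResult:
    """Train/test over every fold and pool confusion counts.

    Features are z-scored per voxel using training-fold statistics only.
    Counts are pooled across folds before a single d-prime computation,
    because per-fold counts (2 test patterns) are too small to score alone.
    """
    if not plan.folds:
        raise ValueError("empty fold plan")
    h = m = fa = cr = 0
    for fold in plan.folds:
        X_train = np.stack([cells[k] for k in fold.train])
        y_train = np.array([1 if k[2] == SIGNAL_CATEGORY else 0 for k in fold.train])
        X_test = np.stack([cells[k] for k in fold.test])
        y_test = np.array([1 if k[2] == SIGNAL_CATEGORY else 0 for k in fold.test])
        if scale:
            mu, sd = _zscore_train_stats(X_train)
            X_train = (X_train - mu) / sd
            X_test = (X_test - mu) / sd
        clf = train_linear_classifier(X_train, y_train)
        pred = clf.predict(X_test)
        h += int(np.sum((y_test == 1) & (pred == 1)))
        m += int(np.sum((y_test == 1) & (pred == 0)))
        fa += int(np.sum((y_test == 0) & (pred == 1)))
        cr += int(np.sum((y_test == 0) & (pred == 0)))
    return DecodingResult(
        subject=subject,
        roi=roi,
        regime=plan.regime,
        h=h,
        m=m,
        fa=fa,
        cr=cr,
        n_folds=len(plan.folds),
        correction=correction,
    )


# ---------------------------------------------------------------------------
# Subject / cohort drivers
# ---------------------------------------------------------------------------

def decode_subject(
    dataset: "RoiDataset",
    mask: "UsabilityMask",
    split: ExemplarSplit | None = None,
    regimes: Sequence[str] = DEFAULT_REGIMES,
    cross_exemplar: bool = True,
    scale: bool = True,
    correction: str = "log_linear",
) -> list[DecodingResult]:
    """Decode every (ROI, regime) for one subject.

    Regimes whose fold plan cannot be formed (fewer than 2 retained runs)
    yield a result with zero folds, which downstream group tests treat as
    missing.
    """
    if split is None:
        split = ExemplarSplit.default()
    cells = make_cell_patterns(dataset, mask, split)
    results: list[DecodingResult] = []
    for regime in regimes:
        try:
            plan = make_fold_plan(regime, mask, cross_exemplar=cross_exemplar)
        except ValueError:
            for roi in dataset.atlas.roi_names:
                results.append(
                    DecodingResult(
                        subject=dataset.subject, roi=roi, regime=regime,
                        h=0, m=0, fa=0, cr=0, n_folds=0, correction=correction,
                    )
                )
            continue
        for roi in dataset.atlas.roi_names:
            results.append(
                evaluate(
                    plan, cells[roi], subject=dataset.subject, roi=roi,
                    scale=scale, correction=correction,
                )
            )
    return results


def results_frame(results: Iterable[DecodingResult]) -> pd.DataFrame:
    """Flatten decoding results into the per-subject results table."""
    rows = [
        {
            "subject": r.subject,
            "roi": r.roi,
            "regime": r.regime,
            "h": r.h,
            "m": r.m,
            "fa": r.fa,
            "cr": r.cr,
            "n_folds": r.n_folds,
            "accuracy": r.accuracy,
            "dprime": r.dprime,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
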