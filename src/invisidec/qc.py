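"""Behavioral exclusion rules applied before decoding.

Three rules, in order:

1. invisible trials with a reported breakthrough are dropped;
2. a (run, method) block of invisible trials is dropped when the subject's
   guess accuracy for that method in that run strictly exceeds 75% (the
   exact one-sided binomial tail probability is computed and logged, but the
   accuracy threshold is the operative rule);
3. a (run, method) block is dropped when, after the first two rules, any
   category x exemplar-set cell has no usable trials left, since the
   per-cell averaged pattern could not be formed.

Fully visible trials are never excluded, regardless of response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import TYPE_CHECKING, Mapping

import numpy as np
import pandas as pd

from .design import CATEGORIES, INVISIBLE_METHODS, METHODS

if TYPE_CHECKING:  # pragma: no cover
    from .decoding import ExemplarSplit
    from .synthetic_data import RoiDataset

REASON_OK = "ok"
REASON_BINOMIAL = "binomial_excluded"
REASON_EXEMPLAR = "insufficient_exemplars"

DEFAULT_ACCURACY_THRESHOLD = 0.75


def binomial_tail(k: int, n: int, p0: float = 0.5) -> float:
    """Exact one-sided upper-tail probability P(X >= k | n, p0).

    Computed by exact probability-mass summation in rational arithmetic
    (floats such as 0.5 or 0.75 are binary-exact), then returned as float.
    """
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0 < p0 < 1:
        raise ValueError(f"p0 must lie strictly in (0, 1), got {p0}")
    p = Fraction(p0)
    q = 1 - p
    total = sum(math.comb(n, i) * p**i * q ** (n - i) for i in range(k, n + 1))
    return float(total)


def flag_breakthrough(events: pd.DataFrame) -> np.ndarray:
    """Trial usability after the breakthrough rule.

    Returns a boolean array aligned with *events* rows: False for invisible
    (CFS/CFF) trials flagged as breakthrough, True otherwise.  Visible
    trials are unaffected — their "breakthrough" button is the required
    clearly-visible report.
    """
    invisible = events["method"].isin(INVISIBLE_METHODS).to_numpy()
    breakthrough = events["breakthrough"].astype(bool).to_numpy()
    return ~(invisible & breakthrough)


def binomial_run_exclusion(
    events: pd.DataFrame,
    threshold: float = DEFAULT_ACCURACY_THRESHOLD,
    pooled: bool = False,
) -> dict[str, dict]:
    """Per-method retention of one run's invisible trials by guess accuracy.

    A method's block is dropped iff observed guess accuracy strictly exceeds
    *threshold*.  With ``pooled=True`` the CFS and CFF guesses are pooled
    into a single accuracy test applied to both methods.  Visible trials are
    always retained and do not appear in the output.

    Returns ``{method: {retained, k, n, accuracy, p}}`` where ``p`` is the
    exact binomial tail probability of *k* or more correct guesses under
    chance.
    """
    correct = events["guess"].to_numpy() == events["category"].to_numpy()
    out: dict[str, dict] = {}

    def _stats(mask: np.ndarray) -> tuple[int, int, float, float]:
        n = int(mask.sum())
        k = int(correct[mask].sum())
        acc = k / n if n else 0.0
        p = binomial_tail(k, n) if n else 1.0
        return k, n, acc, p

    if pooled:
        mask = events["method"].isin(INVISIBLE_METHODS).to_numpy()
        k, n, acc, p = _stats(mask)
        retained = not acc > threshold
        for m in INVISIBLE_METHODS:
            out[m] = {"retained": retained, "k": k, "n": n, "accuracy": acc, "p": p}
    else:
        for m in INVISIBLE_METHODS:
            mask = (events["method"] == m).to_numpy()
            k, n, acc, p = _stats(mask)
            out[m] = {"retained": not acc > threshold, "k": k, "n": n, "accuracy": acc, "p": p}
    return out


def min_exemplar_rule(
    events: pd.DataFrame, usable: np.ndarray, method: str, split: "ExemplarSplit"
) -> bool:
    """True iff every category x exemplar-set cell of *method* has a usable trial.

    This is the weakest condition under which the averaged cell patterns
    used for cross-exemplar classification all exist (and it guarantees at
    least two distinct usable exemplars per category in the run).
    """
    methods = events["method"].to_numpy()
    cats = events["category"].to_numpy()
    exemplars = events["exemplar"].to_numpy()
    for cat in CATEGORIES:
        for label in ("A", "B"):
            in_cell = (
                (methods == method)
                & (cats == cat)
                & np.array([split.label(e) == label for e in exemplars])
            )
            if not np.any(in_cell & usable):
                return False
    return True


@dataclass
class UsabilityMask:
    """Trial- and block-level usability decisions for one subject."""

    trial_usable: dict[int, np.ndarray]
    retained: dict[tuple[int, str], bool]
    reasons: dict[tuple[int, str], str]
    binomial_p: dict[tuple[int, str], float] = field(default_factory=dict)

    def retained_runs(self, method: str) -> list[int]:
        """Sorted run indices whose *method* block survived all rules."""
        return sorted(run for (run, m), ok in self.retained.items() if m == method and ok)

    def usable_in_block(self, events: pd.DataFrame, run: int, method: str) -> np.ndarray:
        """Boolean mask over *events* rows: usable trials of (run, method)."""
        if not self.retained.get((run, method), False):
            return np.zeros(len(events), dtype=bool)
        return self.trial_usable[run] & (events["method"] == method).to_numpy()

    def to_frame(self) -> pd.DataFrame:
        """Block-retention table: run, method, retained, reason, binomial_p."""
        rows = [
            {
                "run": run,
                "method": m,
                "retained": ok,
                "reason": self.reasons[(run, m)],
                "binomial_p": self.binomial_p.get((run, m), float("nan")),
            }
            for (run, m), ok in sorted(self.retained.items())
        ]
        return pd.DataFrame(rows)


def apply_qc(
    dataset: "RoiDataset",
    split: "ExemplarSplit",
    threshold: float = DEFAULT_ACCURACY_THRESHOLD,
    pooled: bool = False,
) -> UsabilityMask:
    """Run all exclusion rules over one subject's runs."""
    trial_usable: dict[int, np.ndarray] = {}
    retained: dict[tuple[int, str], bool] = {}
    reasons: dict[tuple[int, str], str] = {}
    binom_p: dict[tuple[int, str], float] = {}

    for run in dataset.runs:
        events = run.events
        usable = flag_breakthrough(events)
        trial_usable[run.index] = usable
        binom = binomial_run_exclusion(events, threshold=threshold, pooled=pooled)
        for m in METHODS:
            key = (run.index, m)
            if m in binom:
                binom_p[key] = binom[m]["p"]
                if not binom[m]["retained"]:
                    retained[key] = False
                    reasons[key] = REASON_BINOMIAL
                    continue
            if not min_exemplar_rule(events, usable, m, split):
                retained[key] = False
                reasons[key] = REASON_EXEMPLAR
            else:
                retained[key] = True
                reasons[key] = REASON_OK

    # A trial in a dropped block is unusable.
    for run in dataset.runs:
        methods = run.events["method"].to_numpy()
        keep = np.array([retained[(run.index, m)] for m in methods])
        trial_usable[run.index] = trial_usable[run.index] & keep

    return UsabilityMask(
        trial_usable=trial_usable, retained=retained, reasons=reasons, binomial_p=binom_p
    )


def usability_frame(dataset: "RoiDataset", mask: UsabilityMask) -> pd.DataFrame:
    """Long-format per-trial usability table for export."""
    rows = []
    for run in dataset.runs:
        usable = mask.trial_usable[run.index]
        for i, method in enumerate(run.events["method"]):
            ok = bool(usable[i])
            if ok:
                reason = REASON_OK
            elif not mask.retained[(run.index, method)]:
                reason = mask.reasons[(run.index, method)]
            else:
                reason = "breakthrough"
            rows.append({"run": run.index, "trial": i, "usable": ok, "reason": reason})
    return pd.DataFrame(rows)
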