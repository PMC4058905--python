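"""Group-level inference over subject d-primes.

The inference chain: one-sided one-sample t-tests of visible decoding
against chance over the full ROI set, Benjamini-Hochberg FDR at q = 0.05 to
select a gate of visibly decodable ROIs, then the invisible within-method
and all cross-method analyses restricted to that gate, each FDR-corrected
within its own family.  Directional paired t-tests compare methods in ROIs
where at least one of the two regimes was significant.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import METHODS

DEFAULT_Q = 0.05

WITHIN_REGIMES = tuple(f"within:{m}" for m in METHODS)
CONTRAST_PAIRS = (
    ("within:VIS", "within:CFS"),
    ("within:VIS", "within:CFF"),
    ("within:CFF", "within:CFS"),
)


def one_sample_t_onesided(values: Sequence[float], mu0: float = 0.0) -> tuple[float, float]:
    """One-sided (upper tail) one-sample t-test.

    Returns ``(t, p)``; ``(nan, nan)`` with a warning when the variance is
    zero or n < 2, in which case the test is undefined.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    n = len(x)
    if n < 2:
        warnings.warn(f"one-sample t-test needs n >= 2, got {n}", stacklevel=2)
        return float("nan"), float("nan")
    sd = x.std(ddof=1)
    if sd == 0:
        if x.mean() == mu0:
            # Degenerate 0/0 case: no deviation at all, no evidence either way.
            return 0.0, 0.5
        warnings.warn("one-sample t-test undefined for zero variance", stacklevel=2)
        return float("nan"), float("nan")
    t = (x.mean() - mu0) / (sd / np.sqrt(n))
    p = float(stats.t.sf(t, df=n - 1))
    return float(t), p


def paired_t_onesided(
    values_a: Sequence[float],
    values_b: Sequence[float],
    direction: str = "greater",
) -> tuple[float, float]:
    """One-sided paired t-test on a - b.

    ``direction="greater"`` tests mean(a - b) > 0, ``"less"`` the reverse,
    ``"auto"`` takes the direction of the observed mean difference (so p is
    at most 0.5).  Pairs with a missing value on either side are dropped.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    d = a[keep] - b[keep]
    if direction == "less":
        d = -d
    elif direction == "auto":
        if len(d) and np.nanmean(d) < 0:
            d = -d
    elif direction != "greater":
        raise ValueError(f"unknown direction {direction!r}")
    return one_sample_t_onesided(d)


def fdr_bh(pvalues: Sequence[float], q: float = DEFAULT_Q) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up over one family of p-values.

    Returns ``(reject, p_adjusted)`` where adjusted p values are
    ``min_{j >= i} m * p_(j) / j`` capped at 1.  NaN entries are excluded
    from the family (never rejected, adjusted p = NaN).
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1) & ~np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject = np.zeros(p.shape, dtype=bool)
    adj = np.full(p.shape, np.nan)
    valid = ~np.isnan(p)
    m = int(valid.sum())
    if m == 0:
        return reject, adj
    pv = p[valid]
    order = np.argsort(pv, kind="stable")
    ranked = pv[order]
    stepup = ranked * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(stepup[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    passing = np.nonzero(ranked <= np.arange(1, m + 1) * q / m)[0]
    rej_sorted = np.zeros(m, dtype=bool)
    if len(passing):
        rej_sorted[: passing[-1] + 1] = True
    adj_valid = np.empty(m)
    rej_valid = np.empty(m, dtype=bool)
    adj_valid[order] = adj_sorted
    rej_valid[order] = rej_sorted
    adj[valid] = adj_valid
    reject[valid] = rej_valid
    return reject, adj


# ---------------------------------------------------------------------------
# Group tables
# ---------------------------------------------------------------------------

def group_table(
    results: pd.DataFrame,
    regime: str,
    rois: Sequence[str],
    q: float = DEFAULT_Q,
) -> pd.DataFrame:
    """One FDR family: per-ROI group test of a single regime.

    Subjects with missing d-prime (excluded runs) are dropped per ROI, with
    the remaining n reported; degrees of freedom are n - 1.
    """
    rows = []
    sub = results[results["regime"] == regime]
    for roi in rois:
        values = sub.loc[(sub["roi"] == roi) & (sub["n_folds"] > 0), "dprime"].to_numpy()
        values = values[~np.isnan(values)]
        if len(values) >= 2 and values.std(ddof=1) > 0:
            t, p = one_sample_t_onesided(values)
        else:
            t, p = float("nan"), float("nan")
        rows.append(
            {
                "roi": roi,
                "regime": regime,
                "n": len(values),
                "mean_dprime": float(np.mean(values)) if len(values) else float("nan"),
                "t": t,
                "p": p,
            }
        )
    table = pd.DataFrame(rows)
    reject, adj = fdr_bh(table["p"].to_numpy(), q=q)
    table["p_fdr"] = adj
    table["significant"] = reject
    return table


def gate_rois(visible_table: pd.DataFrame) -> list[str]:
    """ROIs whose visible decoding survived FDR (the analysis gate)."""
    gate = visible_table.loc[visible_table["significant"].astype(bool), "roi"].tolist()
    if not gate:
        warnings.warn("no ROI passed the visible gate; downstream analyses are empty", stacklevel=2)
    return gate


def paired_contrasts(
    results: pd.DataFrame,
    within_tables: dict[str, pd.DataFrame],
    pairs: Sequence[tuple[str, str]] = CONTRAST_PAIRS,
    q: float = DEFAULT_Q,
) -> pd.DataFrame:
    """Directional paired tests between regimes, where either was significant.

    For each pair, the test runs in ROIs significant for at least one of the
    two regimes; the direction follows the observed mean difference.  Both
    raw and BH-adjusted p (within each contrast family) are reported.
    """
    rows = []
    for regime_a, regime_b in pairs:
        ta = within_tables.get(regime_a)
        tb = within_tables.get(regime_b)
        if ta is None or tb is None:
            continue
        sig_rois: list[str] = []
        for t in (ta, tb):
            sig_rois += t.loc[t["significant"].astype(bool), "roi"].tolist()
        for roi in sorted(set(sig_rois), key=sig_rois.index):
            a = _subject_values(results, regime_a, roi)
            b = _subject_values(results, regime_b, roi)
            common = sorted(set(a) & set(b))
            va = np.array([a[s] for s in common])
            vb = np.array([b[s] for s in common])
            keep = ~(np.isnan(va) | np.isnan(vb))
            mean_diff = float(np.mean(va[keep] - vb[keep])) if keep.any() else float("nan")
            direction = "greater" if not mean_diff < 0 else "less"
            t_stat, p = paired_t_onesided(va, vb, direction=direction)
            rows.append(
                {
                    "roi": roi,
                    "contrast": f"{regime_a} vs {regime_b}",
                    "direction": direction,
                    "n": int(keep.sum()),
                    "mean_diff": mean_diff,
                    "t": t_stat,
                    "p": p,
                }
            )
    table = pd.DataFrame(
        rows, columns=["roi", "contrast", "direction", "n", "mean_diff", "t", "p"]
    )
    if len(table):
        adj_parts = []
        for _, grp in table.groupby("contrast", sort=False):
            reject, adj = fdr_bh(grp["p"].to_numpy(), q=q)
            adj_parts.append(pd.DataFrame({"p_fdr": adj, "significant": reject}, index=grp.index))
        extra = pd.concat(adj_parts).sort_index()
        table = pd.concat([table, extra], axis=1)
    else:
        table["p_fdr"] = []
        table["significant"] = []
    return table


def _subject_values(results: pd.DataFrame, regime: str, roi: str) -> dict[str, float]:
    sub = results[(results["regime"] == regime) & (results["roi"] == roi) & (results["n_folds"] > 0)]
    return dict(zip(sub["subject"], sub["dprime"]))


@dataclass
class GroupAnalysis:
    """All group tables of one analysis run."""

    visible: pd.DataFrame
    within: pd.DataFrame
    cross: pd.DataFrame
    contrasts: pd.DataFrame
    gate: list[str]
    q: float = DEFAULT_Q

    def significant_rois(self, regime: str) -> frozenset[str]:
        """ROIs significant for a regime (visible, within, or cross)."""
        for table in (self.visible, self.within, self.cross):
            sub = table[table["regime"] == regime]
            if len(sub):
                return frozenset(sub.loc[sub["significant"].astype(bool), "roi"])
        return frozenset()

    def to_report(self) -> dict:
        """Machine-readable report of every table, JSON-serializable."""
        def records(df: pd.DataFrame) -> list[dict]:
            return json.loads(df.to_json(orient="records"))

        return {
            "q": self.q,
            "gate": list(self.gate),
            "visible": records(self.visible),
            "within": records(self.within),
            "cross": records(self.cross),
            "contrasts": records(self.contrasts),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_report(), indent=2, sort_keys=True, **kwargs)


def run_full_analysis(
    results: pd.DataFrame,
    rois: Sequence[str] | None = None,
    q: float = DEFAULT_Q,
) -> GroupAnalysis:
    """The full inference chain over a decoded-results table.

    Visible within-method decoding is tested over all ROIs and
    FDR-corrected; surviving ROIs form the gate.  Invisible within-method
    and every cross-method regime present in *results* are then tested over
    the gate only, each regime re-corrected as its own family.  Missing
    regimes simply produce no rows (a partial report, not an error).
    """
    if rois is None:
        rois = list(dict.fromkeys(results["roi"]))
    regimes = set(results["regime"])
    if "within:VIS" not in regimes:
        raise ValueError("the visible within-method regime is required to form the gate")

    visible = group_table(results, "within:VIS", rois, q=q)
    gate = gate_rois(visible)

    within_tables: dict[str, pd.DataFrame] = {"within:VIS": visible}
    within_parts = []
    for regime in ("within:CFS", "within:CFF"):
        if regime in regimes and gate:
            table = group_table(results, regime, gate, q=q)
            within_tables[regime] = table
            within_parts.append(table)
    within = (
        pd.concat(within_parts, ignore_index=True)
        if within_parts
        else visible.iloc[0:0].copy()
    )

    cross_parts = []
    for regime in sorted(r for r in regimes if r.startswith("cross:")):
        if gate:
            cross_parts.append(group_table(results, regime, gate, q=q))
    cross = (
        pd.concat(cross_parts, ignore_index=True) if cross_parts else visible.iloc[0:0].copy()
    )

    contrasts = paired_contrasts(results, within_tables, q=q)
    return GroupAnalysis(
        visible=visible, within=within, cross=cross, contrasts=contrasts, gate=gate, q=q
    )
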