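"""End-to-end orchestration: simulate -> QC -> decode -> group inference."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import decoding, design, group_inference, qc, synthetic_data
from .decoding import ExemplarSplit
from .group_inference import GroupAnalysis
from .synthetic_data import Cohort, CodingAxes, RoiAtlasSpec

PIPELINE_REGIMES = (
    "within:VIS",
    "within:CFS",
    "within:CFF",
    "cross:CFS-CFF",
    "cross:CFF-CFS",
)


def qc_and_decode_cohort(
    cohort: Cohort,
    split: ExemplarSplit | None = None,
    regimes: Sequence[str] = PIPELINE_REGIMES,
    cross_exemplar: bool = True,
    scale: bool = True,
    correction: str = "log_linear",
    qc_threshold: float = qc.DEFAULT_ACCURACY_THRESHOLD,
    qc_pooled: bool = False,
) -> pd.DataFrame:
    """Apply QC and decode every subject of a cohort into one results table."""
    if split is None:
        split = ExemplarSplit.default()
    all_results: list[decoding.DecodingResult] = []
    for dataset in cohort.datasets:
        mask = qc.apply_qc(dataset, split, threshold=qc_threshold, pooled=qc_pooled)
        all_results.extend(
            decoding.decode_subject(
                dataset,
                mask,
                split=split,
                regimes=regimes,
                cross_exemplar=cross_exemplar,
                scale=scale,
                correction=correction,
            )
        )
    return decoding.results_frame(all_results)


@dataclass
class PipelineRun:
    """One full synthetic-study replication."""

    cohort_manifest: pd.DataFrame
    axes: CodingAxes
    results: pd.DataFrame
    analysis: GroupAnalysis


def run_pipeline(
    n_subjects: int = 17,
    n_runs: int = 8,
    scenario: str = "paper_like",
    seed: int | None = None,
    atlas: RoiAtlasSpec | None = None,
    regimes: Sequence[str] = PIPELINE_REGIMES,
    n_candidates: int = 1000,
    q: float = group_inference.DEFAULT_Q,
    split: ExemplarSplit | None = None,
    axes_kwargs: Mapping | None = None,
    keep_datasets: bool = False,
    **subject_kwargs,
) -> PipelineRun:
    """Simulate a cohort, run QC + decoding, and produce the group tables.

    Deterministic given *seed*; the same configuration and seed yield a
    byte-identical report.
    """
    cohort = synthetic_data.simulate_cohort(
        n_subjects=n_subjects,
        n_runs=n_runs,
        scenario=scenario,
        seed=seed,
        atlas=atlas,
        n_candidates=n_candidates,
        axes_kwargs=axes_kwargs,
        **subject_kwargs,
    )
    results = qc_and_decode_cohort(cohort, split=split, regimes=regimes)
    analysis = group_inference.run_full_analysis(
        results, rois=list(cohort.axes.atlas.roi_names), q=q
    )
    run = PipelineRun(
        cohort_manifest=cohort.manifest, axes=cohort.axes, results=results, analysis=analysis
    )
    if not keep_datasets:
        cohort.datasets.clear()
    return run
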