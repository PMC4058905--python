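from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from invisidec import design, synthetic_data as sd
from invisidec.decoding import ExemplarSplit


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def split():
    return ExemplarSplit.default()


@pytest.fixture(scope="session")
def tiny_atlas():
    """Three small ROIs to keep simulations fast."""
    return sd.RoiAtlasSpec(
        roi_names=("R1", "R2", "R3"), voxels_per_roi={"R1": 12, "R2": 10, "R3": 8}
    )


def make_tiny_axes(atlas, seed=0, **kwargs):
    """Custom axes: signal everywhere for VIS/CFS/CFF in R1 only, by default."""
    amplitudes = {
        (roi, m): (1.0 if roi == "R1" else 0.0) for roi in atlas.roi_names for m in design.METHODS
    }
    rho = {roi: 0.9 for roi in atlas.roi_names}
    amplitudes.update(kwargs.pop("amplitudes", {}))
    rho.update(kwargs.pop("rho", {}))
    return sd.sample_coding_axes(
        atlas, scenario="custom", seed=seed, amplitudes=amplitudes, rho=rho, **kwargs
    )


@pytest.fixture(scope="session")
def tiny_subject(tiny_atlas):
    """One deterministic trial-mode subject with planted signal in R1."""
    rng = np.random.default_rng(999)
    axes = make_tiny_axes(tiny_atlas, seed=0)
    schedules = design.generate_subject_schedules(4, n_candidates=50, rng=rng)
    return sd.simulate_subject("sub-01", schedules, axes, noise_sd=1.0, rng=rng), axes


def behavior_free_events(n_runs=2, seed=0):
    """Schedules plus all-clean behavior (no breakthrough, chance guesses)."""
    rng = np.random.default_rng(seed)
    schedules = design.generate_subject_schedules(n_runs, n_candidates=20, rng=rng)
    out = []
    for s in schedules:
        events = s.to_events()
        events["guess"] = [
            t.category if rng.random() < 0.5 else ("tool" if t.category == "face" else "face")
            for t in s.trials
        ]
        events["breakthrough"] = False
        events["seen"] = events["method"] == "VIS"
        out.append((s, events))
    return out
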