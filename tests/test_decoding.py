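from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.special import erfinv

from invisidec import design, qc, synthetic_data as sd
from invisidec.decoding import (
    DecodingResult,
    ExemplarSplit,
    average_patterns,
    decode_subject,
    dprime,
    evaluate,
    extract_trial_pattern,
    make_cell_patterns,
    make_fold_plan,
    make_folds_cross,
    make_folds_within,
    parse_regime,
    results_frame,
    train_linear_classifier,
    trial_patterns,
)

from conftest import make_tiny_axes


def z_oracle(p):
    """Independent inverse normal CDF via the error function."""
    return float(np.sqrt(2.0) * erfinv(2.0 * p - 1.0))


class TestExemplarSplit:
    def test_default(self):
        s = ExemplarSplit.default()
        assert s.set_a == {1, 2} and s.set_b == {3, 4}
        assert s.label(1) == "A" and s.label(4) == "B"

    def test_invalid_splits(self):
        with pytest.raises(ValueError):
            ExemplarSplit(frozenset({1, 2}), frozenset({2, 3}))
        with pytest.raises(ValueError):
            ExemplarSplit(frozenset({1}), frozenset({2, 3, 4}))

    def test_random_split_valid(self):
        s = ExemplarSplit.random(np.random.default_rng(0))
        assert s.set_a | s.set_b == {1, 2, 3, 4}


class TestExtractTrialPattern:
    def test_mean_of_4s_and_6s_volumes(self):
        series = np.zeros((10, 1))
        series[7] = 2.0  # 14 s
        series[8] = 4.0  # 16 s
        np.testing.assert_allclose(extract_trial_pattern(series, onset=10.0), [3.0])

    def test_constant_series(self):
        series = np.full((20, 3), 7.5)
        np.testing.assert_allclose(extract_trial_pattern(series, onset=8.0), [7.5] * 3)

    def test_too_close_to_end(self):
        series = np.zeros((8, 2))
        with pytest.raises(ValueError):
            extract_trial_pattern(series, onset=12.0)

    def test_noiseless_single_axis_timeseries_recovery(self, tiny_atlas):
        # Extracted pattern ~ a * w * (h(4) + h(6)) / 2 for isolated response.
        axes = make_tiny_axes(tiny_atlas, seed=0)
        schedules = design.generate_subject_schedules(1, n_candidates=10, seed=4)
        dataset = sd.simulate_subject(
            "s", schedules, axes, mode="timeseries", noise_sd=1e-9,
            exemplar_sd=0.0, color_amp=0.0, seed=5,
        )
        run = dataset.runs[0]
        first = run.schedule.trials[0]
        onset = run.schedule.onsets[0]
        got = extract_trial_pattern(run.data["R1"], onset)
        h = sd.double_gamma_hrf(np.array([4.0, 6.0])).mean()
        s = 1.0 if first.category == "face" else -1.0
        expected = s * axes.amplitude("R1", first.method) * axes.axis("R1", first.method) * h
        # Neighbouring responses overlap a little; compare loosely.
        assert np.corrcoef(got, expected)[0, 1] > 0.99 or np.allclose(expected, 0)


class TestAveragePatterns:
    def test_single_trial(self):
        pats = np.arange(12.0).reshape(3, 4)
        np.testing.assert_allclose(average_patterns(pats, np.array([1])), pats[1])

    def test_identical_patterns(self):
        pats = np.tile(np.array([1.0, 2.0]), (4, 1))
        np.testing.assert_allclose(average_patterns(pats, np.array([True] * 4)), [1.0, 2.0])

    def test_opposite_patterns_cancel(self):
        pats = np.array([[1.0, -2.0], [-1.0, 2.0]])
        np.testing.assert_allclose(average_patterns(pats, np.array([0, 1])), [0.0, 0.0])

    def test_empty_cell_raises(self):
        with pytest.raises(ValueError):
            average_patterns(np.zeros((3, 2)), np.zeros(3, dtype=bool))


class TestFoldPlans:
    def test_within_8_runs_16_folds(self):
        plan = make_folds_within(range(8), "VIS")
        assert len(plan) == 16

    def test_within_2_runs_4_folds(self):
        plan = make_folds_within([0, 1], "CFS")
        assert len(plan) == 4

    def test_dropped_run_never_appears(self):
        runs = [r for r in range(8) if r != 5]
        plan = make_folds_within(runs, "CFF")
        assert len(plan) == 14
        for fold in plan.folds:
            assert all(k[0] != 5 for k in fold.train + fold.test)

    def test_fewer_than_2_runs_rejected(self):
        with pytest.raises(ValueError):
            make_folds_within([3], "VIS")

    def test_cross_16_folds(self):
        plan = make_folds_cross("CFS", "CFF", range(8), range(8))
        assert len(plan) == 16

    def test_cross_same_method_rejected(self):
        with pytest.raises(ValueError):
            make_folds_cross("CFS", "CFS", range(8), range(8))

    def test_cross_directions_are_distinct_regimes(self):
        a = make_folds_cross("VIS", "CFS", range(4), range(4))
        b = make_folds_cross("CFS", "VIS", range(4), range(4))
        assert a.regime == "cross:VIS-CFS"
        assert b.regime == "cross:CFS-VIS"
        assert a.regime != b.regime

    def test_cross_no_exemplar_constraint(self):
        plan = make_folds_cross("CFS", "CFF", range(8), range(8), cross_exemplar=False)
        assert len(plan) == 8
        sets = {k[3] for fold in plan.folds for k in fold.train}
        assert sets == {"A", "B"}

    def test_within_fold_hygiene_exhaustive(self):
        # No run and no exemplar set may appear on both sides of any fold.
        for n_runs in range(2, 9):
            for method in design.METHODS:
                plan = make_folds_within(range(n_runs), method)
                for fold in plan.folds:
                    train_runs = {k[0] for k in fold.train}
                    test_runs = {k[0] for k in fold.test}
                    assert not train_runs & test_runs
                    train_sets = {k[3] for k in fold.train}
                    test_sets = {k[3] for k in fold.test}
                    assert not train_sets & test_sets

    def test_cross_fold_run_hygiene(self):
        for runs in itertools.combinations(range(6), 4):
            plan = make_folds_cross("CFS", "CFF", runs, runs)
            for fold in plan.folds:
                assert not {k[0] for k in fold.train} & {k[0] for k in fold.test}

    def test_parse_regime(self):
        assert parse_regime("within:VIS") == ("within", "VIS", "VIS")
        assert parse_regime("cross:CFF-CFS") == ("cross", "CFF", "CFS")
        with pytest.raises(ValueError):
            parse_regime("cross:CFS-CFS")
        with pytest.raises(ValueError):
            parse_regime("banana:VIS")


class TestLinearClassifier:
    def test_symmetric_separable(self):
        u = np.array([1.0, -0.5, 2.0])
        X = np.stack([u, -u])
        clf = train_linear_classifier(X, np.array([1, 0]))
        assert clf.predict(u[None])[0] == 1
        assert clf.predict(-u[None])[0] == 0

    def test_training_point_gets_training_label(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(2, 0.1, (5, 4)), rng.normal(-2, 0.1, (5, 4))])
        y = np.array([1] * 5 + [0] * 5)
        clf = train_linear_classifier(X, y)
        np.testing.assert_array_equal(clf.predict(X), y)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_linear_classifier(np.zeros((4, 2)), np.ones(4))


class TestDprime:
    def test_symmetric_rates_zero(self):
        assert dprime(5, 5, 5, 5) == pytest.approx(0.0)

    def test_uncorrected_known_value(self):
        # HR=0.75, FAR=0.25 -> 2 * z(0.75)
        d = dprime(12, 4, 4, 12, correction="none")
        assert d == pytest.approx(2 * z_oracle(0.75), abs=1e-9)
        assert d == pytest.approx(1.349, abs=1e-3)

    def test_log_linear_perfect_classification(self):
        d = dprime(8, 0, 0, 8)
        expected = z_oracle(8.5 / 9) - z_oracle(0.5 / 9)
        assert d == pytest.approx(expected, abs=1e-9)
        assert d == pytest.approx(3.19, abs=5e-3)

    def test_oracle_grid_agreement(self):
        # z(HR) - z(FAR) against the erfinv-based quantile oracle.
        for h, m, fa, cr in itertools.product((0, 3, 7, 16), repeat=4):
            if h + m == 0 or fa + cr == 0:
                continue
            hr = (h + 0.5) / (h + m + 1)
            far = (fa + 0.5) / (fa + cr + 1)
            assert dprime(h, m, fa, cr) == pytest.approx(
                z_oracle(hr) - z_oracle(far), abs=1e-9
            )

    def test_antisymmetric_under_class_swap(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            h, m, fa, cr = rng.integers(0, 20, 4)
            if h + m == 0 or fa + cr == 0:
                continue
            assert dprime(h, m, fa, cr) == pytest.approx(-dprime(fa, cr, h, m), abs=1e-12)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            dprime(0, 0, 4, 4)

    def test_unknown_correction(self):
        with pytest.raises(ValueError):
            dprime(1, 1, 1, 1, correction="bogus")


class TestEvaluate:
    def test_confusion_count_arithmetic(self):
        r = DecodingResult(subject="s", roi="r", regime="within:VIS",
                           h=12, m=4, fa=4, cr=12, n_folds=16)
        assert r.accuracy == pytest.approx(0.75)
        assert r.n_test == 32

    def test_noiseless_planted_data_perfect(self, tiny_atlas, split):
        axes = make_tiny_axes(tiny_atlas, seed=0)
        rng = np.random.default_rng(3)
        schedules = design.generate_subject_schedules(3, n_candidates=10, rng=rng)
        rates = sd.BehaviorRates(breakthrough_cfs=0.0, breakthrough_cff=0.0)
        dataset = sd.simulate_subject(
            "s", schedules, axes, noise_sd=1e-6, exemplar_sd=0.01, rng=rng, rates=rates
        )
        mask = qc.apply_qc(dataset, split)
        results = decode_subject(dataset, mask, split=split,
                                 regimes=["within:VIS", "within:CFS", "within:CFF"])
        for r in results:
            if r.roi == "R1":
                assert r.accuracy == 1.0
                assert r.h + r.m == r.fa + r.cr  # balanced test classes

    def test_label_permutation_at_chance(self, tiny_subject, split):
        import copy

        dataset = copy.deepcopy(tiny_subject[0])
        rng = np.random.default_rng(17)
        total = correct = 0
        for _ in range(30):
            for run in dataset.runs:
                cats = run.events["category"].to_numpy().copy()
                rng.shuffle(cats)
                run.events["category"] = cats
            mask = qc.apply_qc(dataset, split)
            try:
                res = decode_subject(dataset, mask, split=split, regimes=["within:VIS"])
            except ValueError:
                continue
            for r in res:
                if r.roi == "R1" and r.n_folds:
                    total += r.n_test
                    correct += r.h + r.cr
        assert total > 0
        assert abs(correct / total - 0.5) < 0.1

    def test_empty_plan_rejected(self, split):
        from invisidec.decoding import FoldPlan

        with pytest.raises(ValueError):
            evaluate(FoldPlan(regime="within:VIS", folds=[]), {})

    def test_dprime_monotone_in_amplitude(self, tiny_atlas, split):
        amps = [0.3, 0.8, 2.0]
        means = []
        for a in amps:
            vals = []
            for seed in (0, 1, 2):
                axes = make_tiny_axes(
                    tiny_atlas, seed=0,
                    amplitudes={("R1", m): a for m in design.METHODS},
                )
                rng = np.random.default_rng(seed)
                schedules = design.generate_subject_schedules(4, n_candidates=10, rng=rng)
                rates = sd.BehaviorRates(breakthrough_cfs=0.0, breakthrough_cff=0.0)
                dataset = sd.simulate_subject("s", schedules, axes, noise_sd=1.0,
                                              rng=rng, rates=rates)
                mask = qc.apply_qc(dataset, split)
                res = decode_subject(dataset, mask, split=split, regimes=["within:VIS"])
                vals.append(res[0].dprime)
            means.append(float(np.mean(vals)))
        assert means[0] <= means[1] <= means[2]


class TestDecodeSubject:
    def test_results_frame_columns(self, tiny_subject, split):
        dataset, _ = tiny_subject
        mask = qc.apply_qc(dataset, split)
        frame = results_frame(decode_subject(dataset, mask, split=split,
                                             regimes=["within:VIS", "cross:CFS-CFF"]))
        assert set(frame.columns) == {
            "subject", "roi", "regime", "h", "m", "fa", "cr", "n_folds", "accuracy", "dprime",
        }
        assert len(frame) == 2 * len(dataset.atlas.roi_names)

    def test_insufficient_runs_reported_missing(self, tiny_atlas, split):
        axes = make_tiny_axes(tiny_atlas, seed=0)
        rng = np.random.default_rng(3)
        schedules = design.generate_subject_schedules(2, n_candidates=10, rng=rng)
        # Perfect guessing gets every invisible block binomially excluded.
        rates = sd.BehaviorRates(invisible_accuracy=1.0,
                                 breakthrough_cfs=0.0, breakthrough_cff=0.0)
        dataset = sd.simulate_subject("s", schedules, axes, rng=rng, rates=rates)
        mask = qc.apply_qc(dataset, split)
        res = decode_subject(dataset, mask, split=split, regimes=["within:CFS"])
        assert all(r.n_folds == 0 for r in res)
        assert all(np.isnan(r.dprime) for r in res)
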