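"""AUROC, LOSO machinery, paired statistics, and experiment mechanics."""

import numpy as np
import pytest

import pdwear as pw
from pdwear.evaluation import (EvalResult, activity_group_experiment,
                               compute_auroc, holm_correction,
                               learning_curve_experiment, loso_evaluate,
                               make_model_factory, paired_comparison,
                               sensor_combination_experiment,
                               session_experiment)

from oracles import auroc_bruteforce


class TestAUROC:
    def test_perfect_separation(self):
        assert compute_auroc([0.9, 0.8, 0.7, 0.1], [1, 1, 0, 0]) == 1.0

    def test_three_of_four_pairs_ordered(self):
        assert compute_auroc([0.8, 0.4, 0.6, 0.2], [1, 1, 0, 0]) == 0.75

    def test_inverted_labels_give_zero(self):
        assert compute_auroc([0.9, 0.8, 0.7, 0.1], [0, 0, 1, 1]) == 0.0

    def test_single_class_undefined(self):
        assert compute_auroc([0.5, 0.6], [1, 1]) is None

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 40))
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert compute_auroc(scores, labels) == pytest.approx(
                auroc_bruteforce(scores, labels), abs=1e-12)


class TestPairedComparison:
    def test_identical_samples(self):
        t, p, md = paired_comparison([0.7, 0.8, 0.9], [0.7, 0.8, 0.9])
        assert t == 0.0 and p == 1.0 and md == 0.0

    def test_constant_shift_is_overwhelming(self):
        a = np.linspace(0.6, 0.9, 10)
        t, p, md = paired_comparison(a + 0.1, a)
        assert md == pytest.approx(0.1)
        assert p < 1e-6

    def test_constant_difference_closed_form(self):
        t, p, md = paired_comparison([0.7, 0.8, 0.9], [0.6, 0.7, 0.8])
        # differences are exactly 0.1 with zero variance
        assert np.isinf(t) and t > 0
        assert p == 0.0
        assert md == pytest.approx(0.1)

    def test_too_few_pairs_undefined(self):
        assert paired_comparison([0.7, 0.8], [0.6, 0.7]) == (None, None, None)

    def test_holm_is_monotone_and_bounded(self):
        adj = holm_correction({"a": 0.01, "b": 0.04, "c": 0.03})
        assert adj["a"] <= adj["c"] <= adj["b"] <= 1.0
        assert adj["a"] == pytest.approx(0.03)


class _ScoreByFirstFeature:
    """Stub model: score = first feature (monotone oracle for LOSO plumbing)."""

    def predict_scores(self, X):
        return np.asarray(X)[:, 0]


def _stub_factory(X, y):
    return _ScoreByFirstFeature()


class TestLOSO:
    def test_mean_is_average_of_per_subject_aurocs(self, rng):
        X = rng.random((60, 3))
        y = (X[:, 0] > 0.5).astype(int)
        subjects = np.repeat(["a", "b", "c"], 20)
        res = loso_evaluate(X, y, subjects, _stub_factory)
        assert res.n_subjects_evaluated == 3
        assert res.mean_auroc == pytest.approx(np.mean(res.aurocs))
        assert res.ci_low <= res.mean_auroc <= res.ci_high
        assert all(a == 1.0 for a in res.aurocs)

    def test_all_negative_subject_excluded(self, rng):
        X = rng.random((50, 2))
        y = (X[:, 0] > 0.5).astype(int)
        subjects = np.repeat(["a", "b", "c", "d", "e"], 10)
        y[subjects == "e"] = 0
        res = loso_evaluate(X, y, subjects, _stub_factory)
        assert res.n_subjects_evaluated == 4
        assert ("e", "single-class test labels") in res.excluded

    def test_needs_three_subjects(self, rng):
        X = rng.random((20, 2))
        y = rng.integers(0, 2, 20)
        with pytest.raises(ValueError, match="3 subjects"):
            loso_evaluate(X, y, np.repeat(["a", "b"], 10), _stub_factory)

    def test_high_snr_cohort_reaches_09(self, tremor12):
        res = loso_evaluate(tremor12["X"], tremor12["y"],
                            tremor12["subjects"],
                            make_model_factory("rf", seed=0))
        assert res.mean_auroc >= 0.9

    def test_result_roundtrips_through_json(self, tmp_path, rng):
        X = rng.random((60, 3))
        y = (X[:, 0] > 0.5).astype(int)
        subjects = np.repeat(["a", "b", "c"], 20)
        res = loso_evaluate(X, y, subjects, _stub_factory)
        res.save(tmp_path / "res.json")
        back = EvalResult.load(tmp_path / "res.json")
        assert back == res


class TestExperimentMechanics:
    def test_sensor_conditions_paired_and_sized(self, mechanics_cohort):
        out = sensor_combination_experiment(
            mechanics_cohort["recordings"], mechanics_cohort["annotations"],
            mechanics_cohort["config"], "bradykinesia", family="rf", seed=0)
        res = out["results"]
        assert set(res) == {"hand", "hand_bi", "combo"}
        # identical LOSO splits -> same evaluated subjects across conditions
        subj_sets = {tuple(r.subject_ids) for r in res.values()}
        assert len(subj_sets) == 1
        for pair, cmp_ in out["comparisons"].items():
            assert cmp_["n_pairs"] == len(res[pair[0]].subject_ids)

    def test_missing_location_skips_condition(self, caplog):
        config = pw.CohortConfig(n_subjects=4, tasks=pw.DEFAULT_TASKS[:3],
                                 n_sessions_day1=2, include_day2=False,
                                 locations=("hand",), task_duration_s=15.0,
                                 tremor_prev_mean=0.6, rng_seed=31)
        recordings, annotations = pw.simulate_cohort(config)
        out = sensor_combination_experiment(recordings, annotations, config,
                                            "tremor", family="rf", seed=0,
                                            conditions=("hand", "combo"))
        assert "combo" not in out["results"]

    def test_activity_groups_partition_test_clips(self, mechanics_cohort):
        out = activity_group_experiment(
            mechanics_cohort["recordings"], mechanics_cohort["annotations"],
            mechanics_cohort["config"], "bradykinesia", family="rf", seed=0)
        groups = set(out["results"])
        expected = {g for _, g in mechanics_cohort["config"].tasks}
        assert groups <= expected
        for (g, ref), cmp_ in out["comparisons"].items():
            assert ref == "clinical" and g != "clinical"

    def test_learning_curve_sizes_and_determinism(self, rng):
        X = rng.random((200, 3))
        y = (X[:, 0] + 0.1 * rng.standard_normal(200) > 0.5).astype(int)
        subjects = np.repeat([f"s{i}" for i in range(10)], 20)
        r1 = learning_curve_experiment(X, y, subjects, sizes=(3, 9, 10),
                                       n_repeats=4, seed=5)
        r2 = learning_curve_experiment(X, y, subjects, sizes=(3, 9, 10),
                                       n_repeats=4, seed=5)
        assert set(r1) == {3, 9}  # size 10 >= n_subjects skipped
        assert r1[3].extras == r2[3].extras  # reproducible subset draws
        # size 9 of 10 leaves exactly one test subject per repeat
        assert r1[9].n_subjects_evaluated == 4

    def test_session_experiment_supersets_and_day_partition(self, mechanics_cohort):
        out = session_experiment(
            mechanics_cohort["recordings"], mechanics_cohort["annotations"],
            mechanics_cohort["config"], "bradykinesia", family="rf", seed=0)
        res = out["results"]
        assert any(k.endswith("day2") for k in res), "day-2 arm missing"
        assert "all_vs_session1_day1" in out["comparisons"]

    def test_session_experiment_without_day2_skips_arm(self):
        config = pw.CohortConfig(n_subjects=4, tasks=pw.DEFAULT_TASKS[:2],
                                 n_sessions_day1=2, include_day2=False,
                                 locations=("hand",), task_duration_s=15.0,
                                 brady_prev_mean=0.6, rng_seed=37)
        recordings, annotations = pw.simulate_cohort(config)
        out = session_experiment(recordings, annotations, config,
                                 "bradykinesia", family="rf", seed=0)
        assert all(not k.endswith("day2") for k in out["results"])


class TestNullAndRecovery:
    def test_within_subject_permutation_is_chance(self, tremor12):
        X, y, subjects = tremor12["X"], tremor12["y"], tremor12["subjects"]
        rng = np.random.default_rng(99)
        factory = make_model_factory("rf", seed=0)
        means = []
        for _ in range(6):
            y_perm = y.copy()
            for s in np.unique(subjects):
                idx = np.flatnonzero(subjects == s)
                y_perm[idx] = rng.permutation(y_perm[idx])
            try:
                res = loso_evaluate(X, y_perm, subjects, factory)
            except ValueError:
                continue
            means.append(res.mean_auroc)
        assert np.mean(means) == pytest.approx(0.5, abs=0.07)

    def test_auroc_rises_with_effect_size(self):
        base = dict(n_subjects=8, tasks=pw.DEFAULT_TASKS[:2],
                    n_sessions_day1=1, include_day2=False,
                    locations=("hand",), task_duration_s=20.0,
                    tremor_prev_mean=0.5, rng_seed=55)
        means = []
        for amp, depth in [(0.0, 0.0), (0.02, 0.08), (0.06, 0.25)]:
            config = pw.CohortConfig(tremor_amp_scale=amp,
                                     tremor_mod_depth=depth, **base)
            recordings, annotations = pw.simulate_cohort(config)
            dominant = {s.subject_id: s.dominant_side
                        for s in pw.cohort_subjects(config)}
            clips = pw.assemble_dataset(recordings, annotations, "hand",
                                        dominant_side=dominant)
            import pdwear.features as feat
            table = feat.extract_features_table(clips, "tremor")
            res = loso_evaluate(feat.feature_matrix(table),
                                table["label"].to_numpy(int),
                                table["subject"].to_numpy(),
                                make_model_factory("rf", seed=0))
            means.append(res.mean_auroc)
        assert means[0] < means[1] < means[2]
        assert means[0] == pytest.approx(0.5, abs=0.15)
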