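"""Cohort generator: determinism, counting, prevalence, signal physics."""

import dataclasses

import numpy as np
import pytest

import pdwear as pw
from pdwear.features import dominant_frequency
from pdwear.synthetic import ConfigError, _draw_score, _rng


def small_config(**kw):
    base = dict(n_subjects=2, tasks=pw.DEFAULT_TASKS[:2], n_sessions_day1=1,
                include_day2=False, locations=("hand",), task_duration_s=6.0,
                rng_seed=0)
    base.update(kw)
    return pw.CohortConfig(**base)


class TestConfigAndSubjects:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigError):
            pw.CohortConfig(n_subjects=1)
        with pytest.raises(ConfigError):
            pw.CohortConfig(brady_attenuation=1.5)
        with pytest.raises(ConfigError):
            pw.CohortConfig(tremor_prev_mean=1.2)
        with pytest.raises(ConfigError):
            pw.CohortConfig(n_sessions_day1=0)

    def test_propensities_within_unit_interval(self):
        config = pw.CohortConfig(n_subjects=50, tremor_prev_mean=0.22,
                                 tremor_prev_sd=0.244, rng_seed=3)
        for i in range(50):
            s = pw.draw_subject(config, i)
            assert 0.0 <= s.tremor_propensity <= 1.0
            assert 0.0 <= s.brady_propensity <= 1.0
            assert 4.0 <= s.tremor_freq <= 6.0

    def test_draw_subject_deterministic(self):
        config = small_config()
        assert pw.draw_subject(config, 0) == pw.draw_subject(config, 0)

    def test_zero_sd_collapses_to_mean(self):
        config = pw.CohortConfig(n_subjects=10, tremor_prev_sd=0.0,
                                 brady_prev_sd=0.0, rng_seed=4)
        for i in range(10):
            s = pw.draw_subject(config, i)
            assert s.tremor_propensity == pytest.approx(config.tremor_prev_mean)
            assert s.brady_propensity == pytest.approx(config.brady_prev_mean)


class TestTaskSignal:
    def test_short_duration_rejected(self):
        config = small_config()
        subj = pw.draw_subject(config, 0)
        with pytest.raises(ConfigError):
            pw.simulate_task_signal(subj, "walking", (0, 0), 4.0,
                                    np.random.default_rng(0), config=config)

    def test_channel_shapes_and_ranges(self):
        config = small_config()
        subj = pw.draw_subject(config, 0)
        rec = pw.simulate_task_signal(subj, "walking", (4, 4), 10.0,
                                      np.random.default_rng(0), config=config)
        assert rec.data.shape == (625, 6)
        assert np.all(np.abs(rec.data[:, :3]) <= 4.0)
        assert np.all(np.abs(rec.data[:, 3:]) <= 1000.0)

    def test_severe_tremor_dominates_4_to_6_hz(self):
        config = small_config()
        subj = pw.draw_subject(config, 0)
        hits = 0
        for i in range(50):
            rec = pw.simulate_task_signal(subj, "sitting", (0, 2), 5.0,
                                          np.random.default_rng(500 + i),
                                          config=config, location="hand")
            filt = pw.filter_clip(rec.data, config.sampling_rate, "tremor")
            f = dominant_frequency(np.linalg.norm(filt[:, :3], axis=1),
                                   config.sampling_rate)
            hits += 4.0 <= f <= 6.0
        assert hits >= 48  # >= 95% spectral fidelity

    def test_symptom_free_clip_has_no_tremor_band_peak(self):
        from scipy.signal import periodogram
        config = small_config()
        subj = pw.draw_subject(config, 0)

        def band_peak(severity, seed):
            rec = pw.simulate_task_signal(subj, "sitting", (0, severity), 5.0,
                                          np.random.default_rng(seed),
                                          config=config, location="hand")
            filt = pw.filter_clip(rec.data, config.sampling_rate, "tremor")
            mag = np.linalg.norm(filt[:, :3], axis=1)
            f, p = periodogram(mag - mag.mean(), config.sampling_rate, nfft=512)
            return p[(f >= 4) & (f <= 6)].max()

        quiet = [band_peak(0, s) for s in range(10)]
        tremor = [band_peak(4, s) for s in range(10)]
        assert np.mean(tremor) > 10 * np.mean(quiet)
        # and the argmax of a quiet clip does not sit in the tremor band
        rec = pw.simulate_task_signal(subj, "sitting", (0, 0), 5.0,
                                      np.random.default_rng(0), config=config)
        filt = pw.filter_clip(rec.data, config.sampling_rate, "tremor")
        f = dominant_frequency(np.linalg.norm(filt[:, :3], axis=1),
                               config.sampling_rate)
        assert not (4.0 <= f <= 6.0)

    def test_bradykinesia_attenuates_motion_monotonically(self):
        config = small_config(brady_attenuation=0.5)
        subj = pw.draw_subject(config, 0)
        variances = []
        for sev in range(5):
            rec = pw.simulate_task_signal(subj, "walking", (sev, 0), 5.0,
                                          np.random.default_rng(7),
                                          config=config)
            acc = pw.filter_clip(rec.data, config.sampling_rate, "tremor")[:, :3]
            variances.append(acc.var())
        assert all(np.diff(variances) < 0)


class TestCohort:
    def test_recording_and_annotation_counts(self):
        config = small_config()
        recordings, annotations = pw.simulate_cohort(config)
        # 2 subjects x 2 tasks x 1 session x 1 location x 2 sides
        assert len(recordings) == 8
        assert len(annotations) == 8

    def test_full_study_annotation_count_per_subject(self):
        config = pw.CohortConfig(n_subjects=2, n_sessions_day1=6,
                                 include_day2=True, n_day2_subjects=2,
                                 locations=("hand",), task_duration_s=5.0,
                                 rng_seed=1)
        _, annotations = pw.simulate_cohort(config)
        per_side = [a for a in annotations
                    if a.subject_id == "S000" and a.side == "left"]
        # 13 tasks x 6 day-1 sessions + 13 day-2 tasks
        assert len(per_side) == 13 * 6 + 13

    def test_cohort_files_byte_identical_across_runs(self, tmp_path):
        config = small_config(rng_seed=42)
        sums = []
        for run in ("a", "b"):
            recordings, annotations = pw.simulate_cohort(config)
            out = pw.write_cohort(recordings, annotations, config,
                                  tmp_path / run)
            sums.append(pw.cohort_checksum(out))
        assert sums[0] == sums[1]

    def test_cohort_roundtrip_through_csv(self, tmp_path):
        config = small_config(rng_seed=6)
        recordings, annotations = pw.simulate_cohort(config)
        pw.write_cohort(recordings, annotations, config, tmp_path / "c")
        recs2, anns2, config2 = pw.read_cohort(tmp_path / "c")
        assert config2 == config
        assert len(recs2) == len(recordings)
        assert sorted(a.subject_id for a in anns2) == \
            sorted(a.subject_id for a in annotations)

        def key(r):
            return (r.subject_id, r.day, r.session, r.task, r.side, r.location)
        originals = {key(r): r for r in recordings}
        for r2 in recs2:
            np.testing.assert_allclose(r2.data, originals[key(r2)].data,
                                       atol=1e-5)

    def test_prevalence_recovery_at_scale(self):
        # medication off isolates the prevalence mechanism
        config = pw.CohortConfig(
            n_subjects=200, tasks=pw.DEFAULT_TASKS[:4], n_sessions_day1=2,
            include_day2=False, medication_multiplier=1.0, rng_seed=77)
        frac = {"tremor": [], "brady": []}
        for i in range(config.n_subjects):
            subj = pw.draw_subject(config, i)
            t_hits = b_hits = n = 0
            for day_sess in range(config.n_sessions_day1):
                for ti in range(len(config.tasks)):
                    for bi, side in enumerate(("left", "right")):
                        f = 1.0 if side == subj.dominant_side \
                            else config.nondominant_factor
                        srng = _rng(config.rng_seed, 2, i, 1, day_sess + 1, ti, bi)
                        b = _draw_score(srng, f * subj.brady_propensity, 1.0)
                        t = _draw_score(srng, f * subj.tremor_propensity, 1.0)
                        _draw_score(srng, f * subj.dysk_propensity, 1.0)
                        if side == subj.dominant_side:
                            b_hits += b > 0
                            t_hits += t > 0
                            n += 1
            frac["tremor"].append(t_hits / n)
            frac["brady"].append(b_hits / n)
        assert np.mean(frac["tremor"]) == pytest.approx(
            config.tremor_prev_mean, abs=0.03)
        assert np.mean(frac["brady"]) == pytest.approx(
            config.brady_prev_mean, abs=0.03)

    def test_day2_recordings_are_rotated_versions(self):
        config = small_config(include_day2=True, n_day2_subjects=2,
                              n_sessions_day1=1, day2_rotation_sd_deg=20.0)
        recordings, _ = pw.simulate_cohort(config)
        day2 = [r for r in recordings if r.day == 2]
        assert day2, "day-2 arm missing"
        # rotation preserves the norm of the acc vector
        r = day2[0]
        norms = np.linalg.norm(r.data[:, :3], axis=1)
        assert np.all(norms < 4.0 * np.sqrt(3))
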