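"""Shared cohorts and feature tables; everything generated at test time."""

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

import pdwear as pw
import pdwear.features as feat


def _dominant(config):
    return {s.subject_id: s.dominant_side for s in pw.cohort_subjects(config)}


@pytest.fixture(scope="session")
def tremor12():
    """12-subject hand-only cohort with the default (large) tremor effect,
    plus its tremor feature table — the discrimination workhorse."""
    config = pw.CohortConfig(
        n_subjects=12, tasks=pw.DEFAULT_TASKS[:4], n_sessions_day1=2,
        include_day2=False, locations=("hand",), task_duration_s=30.0,
        rng_seed=11)
    recordings, annotations = pw.simulate_cohort(config)
    clips = pw.assemble_dataset(recordings, annotations, "hand",
                                dominant_side=_dominant(config))
    table = feat.extract_features_table(clips, "tremor")
    return {
        "config": config, "recordings": recordings,
        "annotations": annotations, "clips": clips, "table": table,
        "X": feat.feature_matrix(table),
        "y": table["label"].to_numpy(int),
        "subjects": table["subject"].to_numpy(),
    }


@pytest.fixture(scope="session")
def hetero19():
    """19-subject heterogeneous cohort with a moderate tremor effect, for
    the learning-curve analysis."""
    config = pw.CohortConfig(
        n_subjects=19, tasks=pw.DEFAULT_TASKS[:3], n_sessions_day1=1,
        include_day2=False, locations=("hand",), task_duration_s=30.0,
        tremor_amp_scale=0.03, tremor_mod_depth=0.12, noise_acc_g=0.02,
        rng_seed=19)
    recordings, annotations = pw.simulate_cohort(config)
    clips = pw.assemble_dataset(recordings, annotations, "hand",
                                dominant_side=_dominant(config))
    table = feat.extract_features_table(clips, "tremor")
    return {
        "config": config,
        "X": feat.feature_matrix(table),
        "y": table["label"].to_numpy(int),
        "subjects": table["subject"].to_numpy(),
    }


@pytest.fixture(scope="session")
def mechanics_cohort():
    """Small full-topology cohort (all 3 locations, 2 sessions + day 2)
    for experiment-mechanics checks."""
    config = pw.CohortConfig(
        n_subjects=5, tasks=(pw.DEFAULT_TASKS[0], pw.DEFAULT_TASKS[2],
                             pw.DEFAULT_TASKS[7], pw.DEFAULT_TASKS[10]),
        n_sessions_day1=2, include_day2=True, n_day2_subjects=4,
        task_duration_s=15.0, tremor_prev_mean=0.5, brady_prev_mean=0.6,
        rng_seed=23)
    recordings, annotations = pw.simulate_cohort(config)
    return {"config": config, "recordings": recordings,
            "annotations": annotations, "dominant": _dominant(config)}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
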