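"""Leave-one-subject-out evaluation and the four study experiments.

Population models are trained on all subjects but one and scored on the
held-out subject's clips; AUROC is computed per subject and averaged, with
a 95% t-distribution confidence interval across subjects. Subjects whose
test labels contain a single class (e.g. a subject who never shows tremor)
are excluded per condition, since their AUROC is undefined.

Experiments:

* sensor combinations — single dominant-side hand vs both hands vs
  hand+forearm+thigh unilaterally, paired across identical LOSO splits;
* activity groups — one model over all tasks, test clips stratified by
  task group, each group compared to the clinical tasks;
* learning curve — random training subsets of increasing size, evaluated
  on the left-out subjects and repeated;
* sessions — training on session 1 only vs all day-1 sessions, tested on
  the held-out subject's day-1 or day-2 clips.

Comparisons between paired conditions use the paired t-test on
per-subject AUROCs; no multiple-testing correction is applied by default
(a Holm option exists).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from . import features as feat
from . import preprocess
from .models import ClassifierSpec, train_random_forest, train_cnn

logger = logging.getLogger(__name__)


def compute_auroc(scores, labels):
    """AUROC = fraction of (positive, negative) pairs ordered correctly,
    ties counted 1/2. Returns None (undefined) if one class is absent."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if np.unique(y).size < 2:
        return None
    return float(roc_auc_score(y, s))


def t_confidence_interval(values, confidence: float = 0.95):
    v = np.asarray(values, dtype=float)
    m = float(v.mean())
    if v.size < 2:
        return m, m
    half = stats.t.ppf(0.5 + confidence / 2, v.size - 1) * v.std(ddof=1) / np.sqrt(v.size)
    return m - half, m + half


@dataclass
class EvalResult:
    """Per-subject AUROCs with their mean and 95% CI for one condition."""

    condition: str
    subject_ids: list
    aurocs: list
    mean_auroc: float
    ci_low: float
    ci_high: float
    n_subjects_evaluated: int
    excluded: list = field(default_factory=list)   # (subject, reason)
    extras: dict = field(default_factory=dict)

    @classmethod
    def from_aurocs(cls, condition, per_subject: dict, excluded=None, extras=None):
        subjects = sorted(per_subject)
        aurocs = [per_subject[s] for s in subjects]
        lo, hi = t_confidence_interval(aurocs)
        return cls(condition=condition, subject_ids=subjects, aurocs=aurocs,
                   mean_auroc=float(np.mean(aurocs)), ci_low=lo, ci_high=hi,
                   n_subjects_evaluated=len(subjects),
                   excluded=list(excluded or []), extras=dict(extras or {}))

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path) -> "EvalResult":
        d = json.loads(Path(path).read_text())
        d["excluded"] = [tuple(e) for e in d["excluded"]]
        return cls(**d)


def paired_comparison(a, b):
    """Paired two-sided t-test on per-subject AUROCs.

    Returns (t, p, mean difference a-b); pairs with a missing value in
    either arm are dropped. Fewer than 3 pairs -> (None, None, None).
    Zero-variance nonzero differences give t = +/-inf, p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if a.size < 3:
        return None, None, None
    d = a - b
    md = float(d.mean())
    # constant differences (to float precision) make the t statistic
    # degenerate: report it as +/-inf rather than a rounding-driven number
    if np.allclose(d, md, rtol=0.0, atol=1e-12):
        if md == 0:
            return 0.0, 1.0, 0.0
        return float(np.sign(md) * np.inf), 0.0, md
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p), md


def holm_correction(pvalues: dict) -> dict:
    """Holm step-down adjusted p-values, keyed like the input."""
    items = sorted((p, k) for k, p in pvalues.items() if p is not None)
    out, running = {}, 0.0
    m = len(items)
    for i, (p, k) in enumerate(items):
        running = max(running, min(1.0, (m - i) * p))
        out[k] = running
    return out


def make_model_factory(family: str = "rf", spec: ClassifierSpec | None = None,
                       seed: int = 0):
    """A callable (X, y) -> fitted model for LOSO folds."""
    if family in ("rf", "random_forest"):
        spec = spec or ClassifierSpec(seed=seed)

        def factory(X, y):
            return train_random_forest(X, y, spec)
    elif family == "cnn":
        spec = spec or ClassifierSpec(family="cnn", seed=seed)

        def factory(X, y):
            return train_cnn(X, y, spec)
    else:
        raise ValueError(f"unknown model family {family!r}")
    return factory


def loso_predictions(X, y, subjects, model_factory):
    """Scores for every subject's clips from a model trained on the others.

    Returns (scores_by_subject, excluded): subjects whose fold could not be
    trained (single-class training set) are excluded with a reason.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    subjects = np.asarray(subjects)
    out, excluded = {}, []
    for subj in sorted(set(subjects.tolist())):
        test = subjects == subj
        if np.unique(y[~test]).size < 2:
            excluded.append((subj, "training set single-class"))
            continue
        model = model_factory(X[~test], y[~test])
        out[subj] = (model.predict_scores(X[test]), np.flatnonzero(test))
    return out, excluded


def loso_evaluate(X, y, subjects, model_factory, condition: str = "loso"
                  ) -> EvalResult:
    """Full LOSO: per-subject AUROC, mean, 95% CI; single-class test
    subjects are excluded and reported. Needs >= 3 subjects and >= 2
    evaluable ones."""
    subjects = np.asarray(subjects)
    if len(set(subjects.tolist())) < 3:
        raise ValueError("LOSO evaluation needs at least 3 subjects")
    y = np.asarray(y, dtype=int)
    preds, excluded = loso_predictions(X, y, subjects, model_factory)
    per_subject = {}
    for subj, (scores, idx) in preds.items():
        auc = compute_auroc(scores, y[idx])
        if auc is None:
            excluded.append((subj, "single-class test labels"))
        else:
            per_subject[subj] = auc
    for subj, reason in excluded:
        logger.warning("excluded %s: %s", subj, reason)
    if len(per_subject) < 2:
        raise ValueError("fewer than 2 evaluable subjects; experiment aborted")
    return EvalResult.from_aurocs(condition, per_subject, excluded)


# ---------------------------------------------------------------- experiments

def _dominant_sides(config):
    from .synthetic import cohort_subjects
    return {s.subject_id: s.dominant_side for s in cohort_subjects(config)}


def _feature_table(recordings, annotations, config, sensor_set, symptom):
    clips = preprocess.assemble_dataset(recordings, annotations, sensor_set,
                                        dominant_side=_dominant_sides(config))
    return feat.extract_features_table(clips, symptom)


def _raw_clip_arrays(recordings, annotations, config, sensor_set, symptom):
    clips = preprocess.assemble_dataset(recordings, annotations, sensor_set,
                                        dominant_side=_dominant_sides(config))
    X = np.stack([preprocess.filter_clip(c.data, c.sampling_rate, symptom)
                  for c in clips])
    y = np.array([c.label(symptom) for c in clips])
    subjects = np.array([c.subject_id for c in clips])
    meta = pd.DataFrame({"subject": subjects, "day": [c.day for c in clips],
                         "session": [c.session for c in clips],
                         "task_group": [c.task_group for c in clips]})
    return X, y, subjects, meta


def _table_xys(table: pd.DataFrame):
    return (feat.feature_matrix(table), table["label"].to_numpy(dtype=int),
            table["subject"].to_numpy())


def sensor_combination_experiment(recordings, annotations, config, symptom,
                                  family: str = "rf", seed: int = 0,
                                  conditions=preprocess.SENSOR_SETS,
                                  feature_tables: dict | None = None):
    """LOSO per sensor set with identical subject splits, plus pairwise
    paired t-tests between conditions. Sensor sets whose locations are
    missing from the cohort are skipped with a warning. Precomputed
    feature tables (condition -> DataFrame) may be supplied."""
    feature_tables = feature_tables or {}
    available = {r.location for r in recordings}
    results, tables = {}, {}
    for cond in conditions:
        need = {loc for _, loc in preprocess.resolve_sensor_set(cond, "left")}
        if not need <= available:
            logger.warning("condition %s needs %s; cohort has %s — skipped",
                           cond, sorted(need), sorted(available))
            continue
        if family == "cnn":
            X, y, subjects, _ = _raw_clip_arrays(recordings, annotations,
                                                 config, cond, symptom)
        else:
            table = feature_tables.get(cond)
            if table is None:
                table = _feature_table(recordings, annotations, config,
                                       cond, symptom)
            X, y, subjects = _table_xys(table)
        factory = make_model_factory(family, seed=seed)
        results[cond] = loso_evaluate(X, y, subjects, factory, condition=cond)
        tables[cond] = dict(zip(results[cond].subject_ids, results[cond].aurocs))
    comparisons = {}
    conds = list(results)
    for i in range(len(conds)):
        for j in range(i + 1, len(conds)):
            a, b = conds[i], conds[j]
            shared = sorted(set(tables[a]) & set(tables[b]))
            t, p, md = paired_comparison([tables[a][s] for s in shared],
                                         [tables[b][s] for s in shared])
            comparisons[(a, b)] = {"t": t, "p": p, "mean_diff": md,
                                   "n_pairs": len(shared)}
    return {"results": results, "comparisons": comparisons}


def activity_group_experiment(recordings, annotations, config, symptom,
                              family: str = "rf", seed: int = 0,
                              sensor_set: str = "hand",
                              reference_group: str = "clinical",
                              table: pd.DataFrame | None = None):
    """One model trained on all tasks; test clips stratified by task group.

    Each group gets its own EvalResult (subjects with single-class labels
    in that group are excluded for that group only); every group is
    compared to the clinical structured tasks with a paired t-test.
    A precomputed feature ``table`` for the sensor set may be passed to
    avoid re-extraction."""
    if table is None:
        table = _feature_table(recordings, annotations, config, sensor_set, symptom)
    X, y, subjects = _table_xys(table)
    groups = table["task_group"].to_numpy()
    factory = make_model_factory(family, seed=seed)
    preds, train_excluded = loso_predictions(X, y, subjects, factory)

    group_names = sorted(set(groups.tolist()))
    results = {}
    for g in group_names:
        per_subject, excluded = {}, list(train_excluded)
        for subj, (scores, idx) in preds.items():
            sel = groups[idx] == g
            if not sel.any():
                continue
            auc = compute_auroc(scores[sel], y[idx][sel])
            if auc is None:
                excluded.append((subj, f"single-class labels in group {g}"))
            else:
                per_subject[subj] = auc
        if not per_subject:
            logger.warning("group %s has no evaluable test clips; omitted", g)
            continue
        results[g] = EvalResult.from_aurocs(f"group:{g}", per_subject, excluded)
    comparisons = {}
    if reference_group in results:
        ref = dict(zip(results[reference_group].subject_ids,
                       results[reference_group].aurocs))
        for g, res in results.items():
            if g == reference_group:
                continue
            cur = dict(zip(res.subject_ids, res.aurocs))
            shared = sorted(set(ref) & set(cur))
            t, p, md = paired_comparison([cur[s] for s in shared],
                                         [ref[s] for s in shared])
            comparisons[(g, reference_group)] = {"t": t, "p": p,
                                                 "mean_diff": md,
                                                 "n_pairs": len(shared)}
    return {"results": results, "comparisons": comparisons}


def learning_curve_experiment(X, y, subjects, sizes, n_repeats: int = 50,
                              family: str = "rf", seed: int = 0):
    """Expected AUROC on a new subject vs number of training subjects.

    For each size s and repeat, a random s-subject training set is drawn;
    the model is evaluated per left-out subject. Returns per size an
    EvalResult over repeat-mean AUROCs (CI across repeats) plus the raw
    per-repeat means for paired tests across sizes. Sizes >= n_subjects
    are skipped."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    subjects = np.asarray(subjects)
    all_subjects = np.array(sorted(set(subjects.tolist())))
    rng = np.random.default_rng(seed)
    factory = make_model_factory(family, seed=seed)
    out = {}
    for size in sizes:
        if size >= all_subjects.size:
            logger.warning("size %d >= n_subjects %d; skipped",
                           size, all_subjects.size)
            continue
        repeat_means = []
        for _ in range(n_repeats):
            train_subj = rng.choice(all_subjects, size=size, replace=False)
            train = np.isin(subjects, train_subj)
            if np.unique(y[train]).size < 2:
                continue
            model = factory(X[train], y[train])
            aurocs = []
            for subj in all_subjects[~np.isin(all_subjects, train_subj)]:
                test = subjects == subj
                auc = compute_auroc(model.predict_scores(X[test]), y[test])
                if auc is not None:
                    aurocs.append(auc)
            if aurocs:
                repeat_means.append(float(np.mean(aurocs)))
        res = EvalResult.from_aurocs(
            f"n_train={size}",
            {f"repeat{i:03d}": m for i, m in enumerate(repeat_means)})
        res.extras["per_repeat_mean"] = repeat_means
        out[int(size)] = res
    return out


def session_experiment(recordings, annotations, config, symptom,
                       family: str = "rf", seed: int = 0,
                       sensor_set: str = "hand",
                       table: pd.DataFrame | None = None):
    """Training on session 1 vs all day-1 sessions, tested on day 1 or day 2.

    LOSO over subjects; training data is always day-1 only. Day-2 testing
    is skipped when the cohort has no day-2 clips. Returns the four
    EvalResults plus paired t-tests on the per-subject AUROC change
    (all-sessions minus single-session) per test day."""
    if table is None:
        table = _feature_table(recordings, annotations, config, sensor_set, symptom)
    X, y, subjects = _table_xys(table)
    days = table["day"].to_numpy(dtype=int)
    sessions = table["session"].to_numpy(dtype=int)
    all_subjects = sorted(set(subjects.tolist()))
    factory = make_model_factory(family, seed=seed)

    train_masks = {"session1": (days == 1) & (sessions == 1),
                   "all_sessions": days == 1}
    test_days = [1] + ([2] if (days == 2).any() else [])
    if 2 not in test_days:
        logger.warning("cohort has no day-2 clips; day-2 arm skipped")

    per = {(tc, td): {} for tc in train_masks for td in test_days}
    excluded = []
    for subj in all_subjects:
        is_subj = subjects == subj
        for tc, tmask in train_masks.items():
            train = tmask & ~is_subj
            if np.unique(y[train]).size < 2:
                excluded.append((subj, f"single-class training set ({tc})"))
                continue
            model = factory(X[train], y[train])
            for td in test_days:
                test = is_subj & (days == td)
                if not test.any():
                    continue
                auc = compute_auroc(model.predict_scores(X[test]), y[test])
                if auc is None:
                    excluded.append((subj, f"single-class day-{td} test labels"))
                else:
                    per[(tc, td)][subj] = auc

    results = {f"{tc}_day{td}": EvalResult.from_aurocs(f"{tc}_day{td}", d,
                                                       excluded)
               for (tc, td), d in per.items() if len(d) >= 2}
    comparisons = {}
    for td in test_days:
        a, b = per.get(("all_sessions", td), {}), per.get(("session1", td), {})
        shared = sorted(set(a) & set(b))
        t, p, md = paired_comparison([a[s] for s in shared],
                                     [b[s] for s in shared])
        comparisons[f"all_vs_session1_day{td}"] = {"t": t, "p": p,
                                                   "mean_diff": md,
                                                   "n_pairs": len(shared)}
    return {"results": results, "comparisons": comparisons}
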