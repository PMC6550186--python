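"""Segment recordings into labeled 5-second clips and filter them.

Accelerometer and gyroscope streams are cut into 5-s windows with 50%
overlap; each clip inherits the clinician scores of its task performance
on the evaluated side, binarized (score > 0 -> symptom present). Filtering
uses 4th-order Butterworth designs applied forward-backward (zero phase):
a 0.5 Hz high-pass on the accelerometer channels removes the orientation
(gravity) component for both symptoms, and for bradykinesia an additional
3 Hz low-pass is applied to all channels, since bradykinetic movement
lives below ~3 Hz.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .synthetic import SensorRecording, TaskAnnotation

logger = logging.getLogger(__name__)

CLIP_SECONDS = 5.0
OVERLAP = 0.5
HP_CUTOFF_HZ = 0.5
LP_CUTOFF_HZ = 3.0
VALID_SYMPTOMS = ("bradykinesia", "tremor")


@dataclass
class LabeledClip:
    """One fixed-length multi-channel window with binary symptom labels.

    ``data`` is (clip_len, 6 * n_sensors); channel blocks of six
    (accX..gyroZ) follow the order of ``locations``/``sides``.
    """

    data: np.ndarray
    subject_id: str
    side: str                      # side the labels refer to
    locations: tuple
    day: int
    session: int
    task: str
    task_group: str
    bradykinesia_score: int
    tremor_score: int
    sampling_rate: float
    start_time: float = 0.0

    @property
    def label_bradykinesia(self) -> int:
        return binarize_score(self.bradykinesia_score)

    @property
    def label_tremor(self) -> int:
        return binarize_score(self.tremor_score)

    def label(self, symptom: str) -> int:
        if symptom == "bradykinesia":
            return self.label_bradykinesia
        if symptom == "tremor":
            return self.label_tremor
        raise ValueError(f"unknown symptom {symptom!r}")


def clip_length_samples(sampling_rate: float, clip_seconds: float = CLIP_SECONDS) -> int:
    """Window length in samples: floor(clip_seconds * fs) = 312 at 62.5 Hz."""
    return int(np.floor(clip_seconds * sampling_rate))


def window_starts(n_samples: int, length: int, step: int) -> np.ndarray:
    if n_samples < length:
        return np.empty(0, dtype=int)
    return np.arange(0, n_samples - length + 1, step)


def segment_clips(recording: SensorRecording,
                  clip_seconds: float = CLIP_SECONDS,
                  overlap: float = OVERLAP):
    """Cut a recording into overlapping windows (unlabeled clips).

    Windows start every ``L * (1 - overlap)`` samples (L = 312, step = 156
    at the defaults); a trailing partial window is discarded. A recording
    shorter than one window yields an empty list with a warning.
    """
    L = clip_length_samples(recording.sampling_rate, clip_seconds)
    step = int(round(L * (1.0 - overlap)))
    starts = window_starts(recording.n_samples, L, step)
    if starts.size == 0:
        logger.warning("recording %s/%s/%s shorter than one clip (%d < %d samples)",
                       recording.subject_id, recording.task, recording.location,
                       recording.n_samples, L)
        return []
    return [(int(s), recording.data[s:s + L]) for s in starts]


def _acc_columns(n_channels: int) -> np.ndarray:
    """Accelerometer column indices in a concatenated 6-per-sensor layout."""
    if n_channels % 6:
        raise ValueError(f"expected a multiple of 6 channels, got {n_channels}")
    idx = np.arange(n_channels)
    return idx[(idx % 6) < 3]


def filter_clip(data: np.ndarray, sampling_rate: float, symptom: str,
                order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth filtering of one clip.

    Accelerometer channels are high-passed at 0.5 Hz (both symptoms); for
    bradykinesia all channels are additionally low-passed at 3 Hz. The
    stated order is the designed filter order; forward-backward application
    squares its magnitude response.
    """
    if symptom not in VALID_SYMPTOMS:
        raise ValueError(f"symptom must be one of {VALID_SYMPTOMS}, got {symptom!r}")
    nyq = sampling_rate / 2.0
    if HP_CUTOFF_HZ >= nyq or LP_CUTOFF_HZ >= nyq:
        raise ValueError("filter cutoff at or above Nyquist frequency")
    out = np.array(data, dtype=float, copy=True)
    acc = _acc_columns(out.shape[1])
    # maximal even-reflection padding: the 0.5 Hz high-pass has a ~2 s
    # impulse response, longer than sosfiltfilt's default pad on a 5 s
    # clip, and odd reflection injects edge kinks that leak through the
    # 3 Hz low-pass
    pad = dict(padlen=out.shape[0] - 1, padtype="even", axis=0)
    sos_hp = sps.butter(order, HP_CUTOFF_HZ, btype="highpass",
                        fs=sampling_rate, output="sos")
    out[:, acc] = sps.sosfiltfilt(sos_hp, out[:, acc], **pad)
    if symptom == "bradykinesia":
        sos_lp = sps.butter(order, LP_CUTOFF_HZ, btype="lowpass",
                            fs=sampling_rate, output="sos")
        out = sps.sosfiltfilt(sos_lp, out, **pad)
    return out


def binarize_score(score) -> int:
    """Clinical score 0-4 -> binary label (score > 0 means symptom present)."""
    if not float(score).is_integer() or not 0 <= int(score) <= 4:
        raise ValueError(f"score must be an integer in [0, 4], got {score!r}")
    return int(int(score) > 0)


SENSOR_SETS = ("hand", "hand_bi", "combo")


def resolve_sensor_set(sensor_set, eval_side: str):
    """Map a named sensor set to concrete (side, location) pairs.

    ``hand``    - hand sensor on the evaluated (dominant-symptom) side;
    ``hand_bi`` - hand sensors on both sides;
    ``combo``   - hand + forearm + thigh on the evaluated side.
    An explicit list of (side, location) pairs passes through.
    """
    other = "right" if eval_side == "left" else "left"
    if sensor_set == "hand":
        return [(eval_side, "hand")]
    if sensor_set == "hand_bi":
        return [(eval_side, "hand"), (other, "hand")]
    if sensor_set == "combo":
        return [(eval_side, "hand"), (eval_side, "forearm"), (eval_side, "thigh")]
    return [tuple(p) for p in sensor_set]


def assemble_dataset(recordings, annotations, sensor_set,
                     dominant_side: dict | None = None,
                     clip_seconds: float = CLIP_SECONDS,
                     overlap: float = OVERLAP) -> list[LabeledClip]:
    """Join recordings with their annotations into labeled clips.

    For multi-sensor sets the sample-aligned windows of the selected
    sensors are concatenated channel-wise into one example; labels always
    come from the evaluated side (the subject's dominant-symptom side,
    from ``dominant_side``). Task performances without an annotation are
    excluded with a warning, mirroring the exclusion of unrated data.
    """
    dominant_side = dominant_side or {}
    ann_index: dict[tuple, TaskAnnotation] = {
        (a.subject_id, a.day, a.session, a.task, a.side): a for a in annotations}
    rec_index: dict[tuple, SensorRecording] = {}
    perf_keys = []
    for r in recordings:
        key = (r.subject_id, r.day, r.session, r.task)
        if key not in rec_index:
            perf_keys.append(key)
        rec_index.setdefault(key, {})[(r.side, r.location)] = r

    clips: list[LabeledClip] = []
    for key in perf_keys:
        subj, day, session, task = key
        eval_side = dominant_side.get(subj, "left")
        pairs = resolve_sensor_set(sensor_set, eval_side)
        group = rec_index[key]
        if any(p not in group for p in pairs):
            logger.warning("missing sensor(s) for %s %s d%d s%d; skipped",
                           subj, task, day, session)
            continue
        ann = ann_index.get((subj, day, session, task, eval_side))
        if ann is None:
            logger.warning("no annotation for %s %s d%d s%d side=%s; excluded",
                           subj, task, day, session, eval_side)
            continue
        recs = [group[p] for p in pairs]
        windows = [segment_clips(r, clip_seconds, overlap) for r in recs]
        n_win = min(len(w) for w in windows)
        for wi in range(n_win):
            start = windows[0][wi][0]
            data = np.hstack([w[wi][1] for w in windows])
            clips.append(LabeledClip(
                data=data, subject_id=subj, side=eval_side,
                locations=tuple(pairs), day=day, session=session, task=task,
                task_group=recs[0].task_group,
                bradykinesia_score=ann.bradykinesia_score,
                tremor_score=ann.tremor_score,
                sampling_rate=recs[0].sampling_rate,
                start_time=start / recs[0].sampling_rate))
    return clips
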