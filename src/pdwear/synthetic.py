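"""Synthetic labeled IMU cohorts for upper-extremity symptom detection.

Emulates a clinic study in which people with Parkinson's disease wear
tri-axial accelerometer + gyroscope sensors (62.5 Hz; hand, forearm and
thigh on both sides) while performing short motor tasks, and a clinician
rates bradykinesia, tremor and dyskinesia per task and side on a 0-4 scale.

The signal model is deliberately simple but carries the spectral
signatures the downstream features are designed to detect:

* voluntary movement — band-limited Gaussian noise (0.5-3 Hz), scaled per
  task group and subject, plus a constant 1 G gravity component on the
  accelerometer z axis;
* rest tremor — an amplitude-modulated sinusoid at a subject-specific
  frequency in the 4-6 Hz band, added to hand and forearm channels with
  amplitude proportional to the rated severity;
* bradykinesia — multiplicative attenuation of voluntary-movement
  amplitude and of its upper band edge (spectral centroid), by
  ``attenuation ** severity``;
* medication — a per-session multiplicative reduction of latent severity
  after the first (pre-dose) session of day 1;
* sensor replacement — a small random fixed rotation of each sensor frame
  on day 2.

All randomness derives from ``CohortConfig.rng_seed`` through
per-(subject, day, session, task, side, location) seed sequences, so a
cohort is bit-identical across runs and independent of generation order.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

SAMPLING_RATE_HZ = 62.5
ACC_RANGE_G = 4.0
GYRO_RANGE_DPS = 1000.0
SIDES = ("left", "right")
LOCATIONS = ("hand", "forearm", "thigh")
TASK_GROUPS = ("functional", "clinical", "fine_motor", "gross_motor")
SYMPTOMS = ("bradykinesia", "tremor", "dyskinesia")

#: the 13 standardized motor tasks and their activity groups
DEFAULT_TASKS = (
    ("walking", "functional"),
    ("walking_counting", "functional"),
    ("finger_to_nose", "clinical"),
    ("alternating_hand_movements", "clinical"),
    ("sit_to_stand", "functional"),
    ("sitting", "functional"),
    ("standing", "functional"),
    ("drawing", "fine_motor"),
    ("typing", "fine_motor"),
    ("nuts_and_bolts", "fine_motor"),
    ("pouring_water", "gross_motor"),
    ("organizing_folders", "gross_motor"),
    ("folding_towels", "gross_motor"),
)


class ConfigError(ValueError):
    """Invalid cohort configuration."""


@dataclass(frozen=True)
class CohortConfig:
    """Study-design and effect-size parameters of a simulated cohort.

    Prevalence means/SDs are the across-subject distribution of the
    fraction of task performances showing each symptom (bradykinesia
    0.485 +/- 0.217, tremor 0.22 +/- 0.244, dyskinesia 0.08 +/- 0.115).
    """

    n_subjects: int = 20
    tasks: tuple = DEFAULT_TASKS
    n_sessions_day1: int = 6
    include_day2: bool = True
    n_day2_subjects: int = 15
    locations: tuple = LOCATIONS
    sampling_rate: float = SAMPLING_RATE_HZ
    task_duration_s: float = 30.0

    brady_prev_mean: float = 0.485
    brady_prev_sd: float = 0.217
    tremor_prev_mean: float = 0.22
    tremor_prev_sd: float = 0.244
    dysk_prev_mean: float = 0.08
    dysk_prev_sd: float = 0.115

    # effect sizes
    tremor_amp_scale: float = 0.06      # G per severity unit, hand/forearm acc
    tremor_mod_depth: float = 0.25      # energy-modulation depth per severity unit
    gyro_tremor_scale: float = 250.0    # deg/s of gyro tremor per G of acc tremor
    brady_attenuation: float = 0.7      # per severity unit, in (0, 1)
    baseline_amp_mean: float = 0.15     # G, voluntary-movement scale (hand, functional)
    baseline_amp_sd: float = 0.04
    gyro_per_acc: float = 150.0         # deg/s of gyro motion per G of acc motion
    noise_acc_g: float = 0.01
    noise_gyro_dps: float = 1.0

    medication_multiplier: float = 0.7  # latent-severity multiplier once medicated
    day2_rotation_sd_deg: float = 15.0  # SD of sensor-replacement rotation angle

    # per-task-group scaling of voluntary motion and of symptom expression
    group_motion_scale: tuple = (
        ("functional", 1.0), ("clinical", 0.6),
        ("fine_motor", 0.35), ("gross_motor", 1.2),
    )
    group_symptom_expression: tuple = (
        ("functional", 1.0), ("clinical", 1.0),
        ("fine_motor", 1.0), ("gross_motor", 0.5),
    )
    nondominant_factor: float = 0.4     # propensity scale on the less-affected side

    rng_seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ConfigError("n_subjects must be >= 2")
        if self.n_sessions_day1 < 1:
            raise ConfigError("n_sessions_day1 must be >= 1")
        if not 0.0 < self.brady_attenuation < 1.0:
            raise ConfigError("brady_attenuation must lie in (0, 1)")
        for name in ("brady_prev_mean", "tremor_prev_mean", "dysk_prev_mean"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.task_duration_s <= 0 or self.sampling_rate <= 0:
            raise ConfigError("durations and sampling rate must be positive")
        if not self.tasks:
            raise ConfigError("task list is empty")
        for _, group in self.tasks:
            if group not in TASK_GROUPS:
                raise ConfigError(f"unknown task group {group!r}")

    @property
    def motion_scale(self) -> dict:
        return dict(self.group_motion_scale)

    @property
    def expression(self) -> dict:
        return dict(self.group_symptom_expression)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass(frozen=True)
class SubjectParams:
    """Latent per-subject parameters of the generative model."""

    subject_id: str
    dominant_side: str
    tremor_freq: float               # Hz, in [4, 6]
    brady_propensity: float          # P(symptom present in a task performance)
    tremor_propensity: float
    dysk_propensity: float
    baseline_amp: float              # G
    med_responsiveness: float        # in [0, 1]; 1 = full medication effect


@dataclass
class SensorRecording:
    """One continuous 6-channel IMU stream for a (subject, side, location,
    day, session, task). ``data`` is (n_samples, 6): accX/Y/Z in G then
    gyroX/Y/Z in deg/s."""

    subject_id: str
    side: str
    location: str
    day: int
    session: int
    task: str
    task_group: str
    data: np.ndarray
    sampling_rate: float = SAMPLING_RATE_HZ
    start_time: float = 0.0

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]


@dataclass(frozen=True)
class TaskAnnotation:
    """Clinician rating (0-4 per symptom) of one task performance, per side."""

    subject_id: str
    day: int
    session: int
    task: str
    side: str
    bradykinesia_score: int
    tremor_score: int
    dyskinesia_score: int

    def __post_init__(self):
        for s in (self.bradykinesia_score, self.tremor_score, self.dyskinesia_score):
            if not (isinstance(s, (int, np.integer)) and 0 <= s <= 4):
                raise ValueError(f"scores must be integers in [0, 4], got {s!r}")


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *[int(k) for k in key]])


def _propensity_draw(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Per-subject symptom propensity: Beta with moments matched to the
    configured prevalence mean/SD.

    A Beta keeps the across-subject mean exactly at the configured
    prevalence (a truncated normal would shift it), lives on [0, 1], and
    at tremor-like parameters puts real mass near 0 — subjects who never
    show the symptom, as observed clinically. Degenerate at sd = 0.
    """
    if sd == 0 or mean in (0.0, 1.0):
        return float(mean)
    var = min(sd * sd, 0.999 * mean * (1.0 - mean))
    nu = mean * (1.0 - mean) / var - 1.0
    return float(rng.beta(mean * nu, (1.0 - mean) * nu))


def draw_subject(config: CohortConfig, index: int,
                 rng: np.random.Generator | None = None) -> SubjectParams:
    """Draw the latent parameters for subject ``index``.

    Deterministic given (config.rng_seed, index): the default RNG stream is
    keyed by both, so subjects can be re-derived independently of cohort
    generation order.
    """
    config.validate()
    if index < 0 or index >= config.n_subjects:
        raise ConfigError(f"subject index {index} outside [0, {config.n_subjects})")
    if rng is None:
        rng = _rng(config.rng_seed, 1, index)
    return SubjectParams(
        subject_id=f"S{index:03d}",
        dominant_side=SIDES[int(rng.integers(2))],
        tremor_freq=float(rng.uniform(4.0, 6.0)),
        brady_propensity=_propensity_draw(rng, config.brady_prev_mean, config.brady_prev_sd),
        tremor_propensity=_propensity_draw(rng, config.tremor_prev_mean, config.tremor_prev_sd),
        dysk_propensity=_propensity_draw(rng, config.dysk_prev_mean, config.dysk_prev_sd),
        baseline_amp=float(max(0.02, rng.normal(config.baseline_amp_mean,
                                                config.baseline_amp_sd))),
        med_responsiveness=float(rng.uniform(0.5, 1.0)),
    )


def cohort_subjects(config: CohortConfig) -> list[SubjectParams]:
    """All subjects of the cohort, in index order (deterministic)."""
    return [draw_subject(config, i) for i in range(config.n_subjects)]


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float,
                       f_lo: float, f_hi: float, n_channels: int) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise, (n, n_channels)."""
    white = rng.standard_normal((n, n_channels))
    sos = sps.butter(2, [f_lo, f_hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, white, axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return x / sd


def simulate_task_signal(subject: SubjectParams, task: str,
                         severity: tuple[int, int], duration_s: float,
                         rng: np.random.Generator, *,
                         config: CohortConfig,
                         location: str = "hand", side: str | None = None,
                         day: int = 1, session: int = 1) -> SensorRecording:
    """Simulate one 6-channel recording of a task performance.

    ``severity`` is (bradykinesia 0-4, tremor 0-4). Tremor is expressed on
    hand and forearm sensors only; bradykinesia attenuates voluntary motion
    everywhere. Requires ``duration_s`` of at least one clip (5 s).
    """
    if duration_s < 5.0:
        raise ConfigError(f"duration {duration_s} s is shorter than one 5-s clip")
    s_brady, s_trem = severity
    fs = config.sampling_rate
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    group = dict(config.tasks).get(task, "functional")
    expr = config.expression.get(group, 1.0)
    motion = config.motion_scale.get(group, 1.0)

    atten = config.brady_attenuation ** (s_brady * expr)
    f_hi = max(0.8, 0.5 + 2.5 * atten)          # spectral-content reduction
    amp_acc = subject.baseline_amp * motion * atten

    acc = amp_acc * _bandlimited_noise(rng, n, fs, 0.5, f_hi, 3)
    gyro = (amp_acc * config.gyro_per_acc) * _bandlimited_noise(rng, n, fs, 0.5, f_hi, 3)

    if s_trem > 0 and location in ("hand", "forearm"):
        # Tremor enters two ways: bursts of muscle activity modulate the
        # overall movement energy at the tremor frequency (so the signal
        # magnitude itself oscillates at f0), and an amplitude-modulated
        # sinusoidal carrier rides on the x/y axes.
        a = config.tremor_amp_scale * s_trem * expr
        if location == "forearm":
            a *= 0.7
        f0 = subject.tremor_freq
        phases = rng.uniform(0, 2 * np.pi, size=5)
        depth = min(0.95, config.tremor_mod_depth * s_trem * expr)
        mod = 1.0 + depth * np.sin(2 * np.pi * f0 * t + phases[0])
        acc *= mod[:, None]
        gyro *= mod[:, None]
        env = 1.0 + 0.3 * np.sin(2 * np.pi * 0.4 * t + phases[1])
        carrier = np.sin(2 * np.pi * f0 * t + phases[2])
        carrier_y = np.sin(2 * np.pi * f0 * t + phases[3])
        acc[:, 0] += a * env * carrier
        acc[:, 1] += 0.6 * a * env * carrier_y
        g_amp = a * config.gyro_tremor_scale
        gyro[:, 0] += g_amp * env * carrier
        gyro[:, 1] += 0.6 * g_amp * env * np.sin(2 * np.pi * f0 * t + phases[4])

    acc[:, 2] += 1.0  # gravity on z; a 0.5 Hz high-pass removes it downstream
    acc += rng.normal(0.0, config.noise_acc_g, size=acc.shape)
    gyro += rng.normal(0.0, config.noise_gyro_dps, size=gyro.shape)

    data = np.hstack([np.clip(acc, -ACC_RANGE_G, ACC_RANGE_G),
                      np.clip(gyro, -GYRO_RANGE_DPS, GYRO_RANGE_DPS)])
    return SensorRecording(subject_id=subject.subject_id, side=side or "left",
                           location=location, day=day, session=session,
                           task=task, task_group=group, data=data,
                           sampling_rate=fs)


def _rotation_matrix(rng: np.random.Generator, angle_sd_deg: float) -> np.ndarray:
    """Small random rotation: random axis, N(0, sd) angle (Rodrigues)."""
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    theta = np.deg2rad(rng.normal(0.0, angle_sd_deg))
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)


def _draw_score(rng: np.random.Generator, propensity: float, med_mult: float) -> int:
    """Presence ~ Bernoulli(propensity); latent severity in [0.5, 4.5),
    scaled by the medication multiplier, then rounded to the 0-4 scale."""
    if rng.random() >= propensity:
        rng.uniform()  # keep stream length fixed across branches
        return 0
    latent = rng.uniform(0.5, 4.4999) * med_mult
    return int(np.clip(np.floor(latent + 0.5), 0, 4))


def simulate_cohort(config: CohortConfig):
    """Generate a full cohort.

    Returns ``(recordings, annotations)``: one :class:`SensorRecording` per
    (subject x side x location x session x task) and one
    :class:`TaskAnnotation` per (subject x day/session x task x side).
    Day 2 (single session, sensors re-applied with a random rotation,
    subjects on their regular medication) covers the first
    ``n_day2_subjects`` subjects only.
    """
    config.validate()
    recordings: list[SensorRecording] = []
    annotations: list[TaskAnnotation] = []
    seed = config.rng_seed

    for si in range(config.n_subjects):
        subj = draw_subject(config, si)
        day2 = config.include_day2 and si < config.n_day2_subjects
        sessions = [(1, s) for s in range(1, config.n_sessions_day1 + 1)]
        if day2:
            sessions.append((2, 1))

        # fixed sensor-replacement rotation per (side, location) on day 2
        rotations = {}
        for bi, side in enumerate(SIDES):
            for li, loc in enumerate(config.locations):
                rotations[(side, loc)] = _rotation_matrix(
                    _rng(seed, 4, si, bi, li), config.day2_rotation_sd_deg)

        for day, session in sessions:
            if day == 1 and session == 1:
                med = 1.0  # pre-dose (OFF) baseline
            else:
                med = 1.0 - subj.med_responsiveness * (1.0 - config.medication_multiplier)
            for ti, (task, group) in enumerate(config.tasks):
                for bi, side in enumerate(SIDES):
                    dom = side == subj.dominant_side
                    f = 1.0 if dom else config.nondominant_factor
                    srng = _rng(seed, 2, si, day, session, ti, bi)
                    scores = (
                        _draw_score(srng, f * subj.brady_propensity, med),
                        _draw_score(srng, f * subj.tremor_propensity, med),
                        _draw_score(srng, f * subj.dysk_propensity, med),
                    )
                    annotations.append(TaskAnnotation(
                        subject_id=subj.subject_id, day=day, session=session,
                        task=task, side=side, bradykinesia_score=scores[0],
                        tremor_score=scores[1], dyskinesia_score=scores[2]))
                    for li, loc in enumerate(config.locations):
                        rrng = _rng(seed, 3, si, day, session, ti, bi, li)
                        rec = simulate_task_signal(
                            subj, task, (scores[0], scores[1]),
                            config.task_duration_s, rrng, config=config,
                            location=loc, side=side, day=day, session=session)
                        if day == 2:
                            R = rotations[(side, loc)]
                            rec.data[:, :3] = rec.data[:, :3] @ R.T
                            rec.data[:, 3:] = rec.data[:, 3:] @ R.T
                        recordings.append(rec)
    return recordings, annotations


# ---------------------------------------------------------------------------
# on-disk cohort layout: one CSV per recording + annotations.csv + config echo

CSV_COLUMNS = "t,accX,accY,accZ,gyroX,gyroY,gyroZ"


def recording_filename(rec: SensorRecording) -> str:
    return (f"{rec.subject_id}_d{rec.day}_s{rec.session}_{rec.task}"
            f"_{rec.side}_{rec.location}.csv")


def write_cohort(recordings, annotations, config: CohortConfig, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(config.to_json())
    with open(outdir / "annotations.csv", "w") as fh:
        fh.write("subject,day,session,task,side,bradykinesia,tremor,dyskinesia\n")
        for a in annotations:
            fh.write(f"{a.subject_id},{a.day},{a.session},{a.task},{a.side},"
                     f"{a.bradykinesia_score},{a.tremor_score},{a.dyskinesia_score}\n")
    rec_dir = outdir / "recordings"
    rec_dir.mkdir(exist_ok=True)
    for rec in recordings:
        t = np.arange(rec.n_samples) / rec.sampling_rate + rec.start_time
        arr = np.column_stack([t, rec.data])
        np.savetxt(rec_dir / recording_filename(rec), arr, fmt="%.6f",
                   delimiter=",", header=CSV_COLUMNS, comments="")
    return outdir


def read_cohort(indir):
    """Read a cohort written by :func:`write_cohort`."""
    indir = Path(indir)
    config_d = json.loads((indir / "config.json").read_text())
    config_d["tasks"] = tuple(tuple(t) for t in config_d["tasks"])
    for k in ("locations", "group_motion_scale", "group_symptom_expression"):
        config_d[k] = tuple(tuple(v) if isinstance(v, list) else v
                            for v in config_d[k])
    config = CohortConfig(**config_d)
    task_group = dict(config.tasks)
    annotations = []
    with open(indir / "annotations.csv") as fh:
        next(fh)
        for line in fh:
            subj, day, sess, task, side, b, tr, dy = line.strip().split(",")
            annotations.append(TaskAnnotation(subj, int(day), int(sess), task,
                                              side, int(b), int(tr), int(dy)))
    recordings = []
    for path in sorted((indir / "recordings").glob("*.csv")):
        subj, d, s, *task_parts, side, loc = path.stem.split("_")
        task = "_".join(task_parts)
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        recordings.append(SensorRecording(
            subject_id=subj, side=side, location=loc, day=int(d[1:]),
            session=int(s[1:]), task=task,
            task_group=task_group.get(task, "functional"),
            data=arr[:, 1:], sampling_rate=config.sampling_rate,
            start_time=float(arr[0, 0])))
    return recordings, annotations, config


def cohort_checksum(outdir) -> str:
    """SHA-256 over all cohort files (sorted); used for determinism checks
    and stage caching."""
    h = hashlib.sha256()
    for path in sorted(Path(outdir).rglob("*")):
        if path.is_file():
            h.update(path.name.encode())
            h.update(path.read_bytes())
    return h.hexdigest()
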