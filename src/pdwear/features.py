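"""The 56-feature clip representation (28 per modality, acc and gyro).

Per modality: per-axis range, skew and excess kurtosis (9); normalized
cross-correlation peak and lag for the three axis pairs (6); dominant
frequency and the first four moments of the power spectrum of the signal
magnitude (5); RMS of the mean-subtracted magnitude ("relative
magnitude", 1); the four distributional moments of the jerk (differenced
signal) magnitude (4); and per-axis sample entropy (3).

Degenerate inputs (zero-variance channels, zero total power) return 0 for
the affected entries instead of NaN; :func:`extract_feature_vector` can
report which entries were degenerate. Feature names are stable and ordered:
the schema is part of the on-disk format.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from scipy import signal as sps

SAMPEN_M = 2
SAMPEN_R_FACTOR = 0.2
SPECTRUM_NFFT = 512        # >= fs / 0.25 -> resolution below 0.25 Hz at 62.5 Hz
SPECTRUM_FMIN = 0.25       # search floor for the dominant frequency, Hz

_PAIRS = (("x", "y", 0, 1), ("x", "z", 0, 2), ("y", "z", 1, 2))

#: per-modality feature names, in schema order
MODALITY_FEATURES = tuple(
    [f"range_{a}" for a in "xyz"]
    + [f"skew_{a}" for a in "xyz"]
    + [f"kurtosis_{a}" for a in "xyz"]
    + [f"xcorr_peak_{a}{b}" for a, b, _, _ in _PAIRS]
    + [f"xcorr_lag_{a}{b}" for a, b, _, _ in _PAIRS]
    + ["dominant_frequency", "relative_magnitude"]
    + [f"psd_moment_{i}" for i in range(1, 5)]
    + [f"jerk_moment_{i}" for i in range(1, 5)]
    + [f"sample_entropy_{a}" for a in "xyz"]
)
assert len(MODALITY_FEATURES) == 28


def feature_names(sensors=("hand",)) -> list[str]:
    """Full schema for a clip: ``<location>_<modality>_<feature>`` per sensor."""
    names = []
    for loc in sensors:
        for mod in ("acc", "gyro"):
            names.extend(f"{loc}_{mod}_{f}" for f in MODALITY_FEATURES)
    return names


def _skew_kurt(x: np.ndarray):
    """Biased standardized third moment and excess fourth moment (the
    scipy.stats.skew / kurtosis(fisher=True) conventions)."""
    d = x - x.mean()
    m2 = np.mean(d * d)
    if m2 == 0:
        return 0.0, 0.0
    d2 = d * d
    skew = float(np.mean(d2 * d) / m2 ** 1.5)
    kurt = float(np.mean(d2 * d2) / (m2 * m2) - 3.0)
    return skew, kurt


def axis_stats(x: np.ndarray):
    """(range, skew, excess kurtosis) of one channel; zero-variance
    channels get skew = kurtosis = 0."""
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 samples")
    rng = float(np.ptp(x))
    skew, kurt = _skew_kurt(x)
    return rng, skew, kurt


def xcorr_features(a: np.ndarray, b: np.ndarray, sampling_rate: float):
    """Peak of the normalized cross-correlation over all lags and its lag
    in seconds. Both series are mean-subtracted; normalization by
    L * sd(a) * sd(b) makes the zero-lag self-correlation exactly 1.
    Ties at the peak resolve toward the smallest absolute lag.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("series must have equal length >= 2")
    a0, b0 = a - a.mean(), b - b.mean()
    sa, sb = a0.std(), b0.std()
    if sa == 0 or sb == 0:
        return 0.0, 0.0
    r = sps.correlate(a0, b0, mode="full") / (a.size * sa * sb)
    lags = sps.correlation_lags(a.size, b.size, mode="full")
    peak = r.max()
    at_peak = lags[np.isclose(r, peak, rtol=0.0, atol=1e-12)]
    lag = at_peak[np.argmin(np.abs(at_peak))]
    return float(peak), float(lag / sampling_rate)


def _spectrum(mag: np.ndarray, sampling_rate: float):
    # Hann-windowed periodogram: leakage sidelobes would otherwise skew
    # the spectral moments of narrowband signals
    x = np.asarray(mag, dtype=float)
    x = x - x.mean()
    nfft = max(SPECTRUM_NFFT, x.size)
    return sps.periodogram(x, fs=sampling_rate, window="hann", nfft=nfft,
                           detrend=False)


def dominant_frequency(mag: np.ndarray, sampling_rate: float) -> float:
    """Argmax frequency (Hz) of the periodogram of the mean-subtracted
    magnitude, searched above 0.25 Hz; zero-padded so the bin width is
    below 0.25 Hz. All-zero input returns 0."""
    if np.asarray(mag).size < 64:
        raise ValueError("need at least 64 samples")
    f, p = _spectrum(mag, sampling_rate)
    if p.sum() == 0:
        return 0.0
    mask = f > SPECTRUM_FMIN - 1e-12
    return float(f[mask][np.argmax(p[mask])])


def psd_moments(mag: np.ndarray, sampling_rate: float):
    """First four moments of the normalized power spectrum treated as a
    distribution over frequency: mean (Hz), variance (Hz^2), skewness and
    excess kurtosis. Zero total power (or a point-mass spectrum, for the
    standardized moments) yields zeros."""
    f, p = _spectrum(mag, sampling_rate)
    total = p.sum()
    if total == 0:
        return 0.0, 0.0, 0.0, 0.0
    w = p / total
    mu = float(np.sum(f * w))
    var = float(np.sum((f - mu) ** 2 * w))
    if var < 1e-12:
        return mu, var, 0.0, 0.0
    skew = float(np.sum((f - mu) ** 3 * w) / var ** 1.5)
    kurt = float(np.sum((f - mu) ** 4 * w) / var ** 2 - 3.0)
    return mu, var, skew, kurt


def jerk_moments(channels: np.ndarray, sampling_rate: float):
    """Moments of the jerk-magnitude series.

    Jerk is the first difference of each axis times the sampling rate
    (G/s for acc); its per-sample Euclidean norm across axes gives the
    magnitude series, summarized by (mean, variance, skew, excess
    kurtosis). A constant-magnitude jerk (e.g. a pure ramp) has zero
    variance and zero higher moments."""
    x = np.asarray(channels, dtype=float)
    if x.shape[0] < 5:
        raise ValueError("need at least 5 samples")
    jerk = np.diff(x, axis=0) * sampling_rate
    jm = np.linalg.norm(jerk, axis=1)
    mean = float(jm.mean())
    var = float(jm.var())
    if var < 1e-20:
        return mean, 0.0, 0.0, 0.0
    skew, kurt = _skew_kurt(jm)
    return mean, var, skew, kurt


def relative_magnitude(channels: np.ndarray) -> float:
    """RMS of the mean-subtracted Euclidean magnitude: movement intensity
    relative to the clip's own baseline."""
    x = np.asarray(channels, dtype=float)
    mag = np.linalg.norm(x, axis=1) if x.ndim == 2 else np.abs(x)
    return float(np.sqrt(np.mean((mag - mag.mean()) ** 2)))


def sample_entropy(x: np.ndarray, m: int = SAMPEN_M,
                   r_factor: float = SAMPEN_R_FACTOR) -> float:
    """SampEn(m, r) with r = r_factor * SD, Chebyshev distance, self-matches
    excluded: -ln(A/B) where B (A) counts template pairs of length m (m+1)
    within r among the first N-m templates.

    Zero-variance series return 0 (r would be 0); if either count is zero
    the value is capped at ln of the number of countable pairs.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < m + 2:
        raise ValueError(f"need at least m + 2 = {m + 2} samples")
    sd = x.std()
    if sd == 0:
        return 0.0
    r = r_factor * sd
    M = n - m  # number of templates of length m + 1
    d = np.abs(x[:, None] - x[None, :])
    dm = d[:M, :M].copy()
    for k in range(1, m):
        np.maximum(dm, d[k:k + M, k:k + M], out=dm)
    dm1 = np.maximum(dm, d[m:m + M, m:m + M])
    # matrices are symmetric with a zero diagonal: pair counts halve the
    # off-diagonal matches (self-matches excluded)
    B = (int(np.count_nonzero(dm <= r)) - M) // 2
    A = (int(np.count_nonzero(dm1 <= r)) - M) // 2
    if A == 0 or B == 0:
        return float(np.log(M * (M - 1) / 2))
    return float(-np.log(A / B))


def modality_features(channels: np.ndarray, sampling_rate: float) -> np.ndarray:
    """The 28 features of one tri-axial modality, in schema order."""
    x = np.asarray(channels, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError(f"expected (n, 3) channels, got {x.shape}")
    out = []
    per_axis = [axis_stats(x[:, i]) for i in range(3)]
    out += [s[0] for s in per_axis]
    out += [s[1] for s in per_axis]
    out += [s[2] for s in per_axis]
    xc = [xcorr_features(x[:, i], x[:, j], sampling_rate) for _, _, i, j in _PAIRS]
    out += [c[0] for c in xc]
    out += [c[1] for c in xc]
    mag = np.linalg.norm(x, axis=1)
    out.append(dominant_frequency(mag, sampling_rate))
    out.append(relative_magnitude(x))
    out += list(psd_moments(mag, sampling_rate))
    out += list(jerk_moments(x, sampling_rate))
    out += [sample_entropy(x[:, i]) for i in range(3)]
    return np.asarray(out, dtype=float)


def extract_feature_vector(data: np.ndarray, sampling_rate: float) -> np.ndarray:
    """56 features per sensor from a filtered clip.

    ``data`` is (clip_len, 6 * n_sensors); each 6-channel block (acc x/y/z,
    gyro x/y/z) contributes 28 acc + 28 gyro features, concatenated across
    sensors. The result is always finite.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] % 6:
        raise ValueError(f"expected (n, 6k) clip data, got {data.shape}")
    blocks = []
    for s in range(data.shape[1] // 6):
        block = data[:, 6 * s:6 * s + 6]
        blocks.append(modality_features(block[:, :3], sampling_rate))
        blocks.append(modality_features(block[:, 3:6], sampling_rate))
    vec = np.concatenate(blocks)
    assert np.all(np.isfinite(vec))
    return vec


def extract_features_table(clips, symptom: str) -> pd.DataFrame:
    """Filter each clip for ``symptom`` and extract its feature vector.

    Returns a DataFrame with metadata columns (subject, side, day, session,
    task, task_group, start_time, label) followed by the feature schema.
    """
    from .preprocess import filter_clip

    rows, meta = [], []
    names = None
    for clip in clips:
        filt = filter_clip(clip.data, clip.sampling_rate, symptom)
        rows.append(extract_feature_vector(filt, clip.sampling_rate))
        if names is None:
            names = feature_names([f"{s}-{l}" for s, l in clip.locations])
        meta.append({
            "subject": clip.subject_id, "side": clip.side, "day": clip.day,
            "session": clip.session, "task": clip.task,
            "task_group": clip.task_group, "start_time": clip.start_time,
            "label": clip.label(symptom),
        })
    if not rows:
        return pd.DataFrame()
    return pd.concat([pd.DataFrame(meta),
                      pd.DataFrame(np.vstack(rows), columns=names)], axis=1)


META_COLUMNS = ("subject", "side", "day", "session", "task", "task_group",
                "start_time", "label")


def feature_matrix(table: pd.DataFrame) -> np.ndarray:
    """The numeric feature block of an extracted table."""
    cols = [c for c in table.columns if c not in META_COLUMNS]
    return table[cols].to_numpy(dtype=float)


def feature_manifest(sensors=("hand",)) -> str:
    """JSON description of the schema: names, units and definitions."""
    defs = {
        "range": "max - min per axis",
        "skew": "standardized third central moment per axis",
        "kurtosis": "excess (Fisher) kurtosis per axis",
        "xcorr_peak": "max normalized cross-correlation over all lags, axis pair",
        "xcorr_lag": "lag (s) of the cross-correlation peak; ties toward 0",
        "dominant_frequency": "periodogram argmax (Hz) of mean-subtracted magnitude, > 0.25 Hz",
        "relative_magnitude": "RMS of mean-subtracted Euclidean magnitude",
        "psd_moment": "spectral mean (Hz), variance (Hz^2), skewness, excess kurtosis "
                      "of the normalized power spectrum over frequency",
        "jerk_moment": "mean, variance, skewness, excess kurtosis of the "
                       "jerk-magnitude series (per-axis first difference x fs, then norm)",
        "sample_entropy": "SampEn(m=2, r=0.2 SD), Chebyshev distance, "
                          "self-matches excluded, per axis",
    }
    return json.dumps({"names": feature_names(sensors), "definitions": defs,
                       "per_sensor": len(MODALITY_FEATURES) * 2}, indent=2)
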