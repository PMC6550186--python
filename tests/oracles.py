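"""Independent brute-force reference implementations used only by tests.

These deliberately use naive double loops / exhaustive enumeration so they
share no code path with the package implementations they check.
"""

import numpy as np


def sampen_bruteforce(x, m=2, r_factor=0.2):
    """SampEn by explicit double-loop template counting (Chebyshev
    distance, self-matches excluded, first N-m templates for both lengths)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    sd = x.std()
    if sd == 0:
        return 0.0
    r = r_factor * sd
    M = n - m
    B = A = 0
    for i in range(M):
        for j in range(i + 1, M):
            db = max(abs(x[i + k] - x[j + k]) for k in range(m))
            if db <= r:
                B += 1
            da = max(db, abs(x[i + m] - x[j + m]))
            if da <= r:
                A += 1
    if A == 0 or B == 0:
        return float(np.log(M * (M - 1) / 2))
    return float(-np.log(A / B))


def auroc_bruteforce(scores, labels):
    """AUROC by exhaustive (positive, negative) pair counting, ties = 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        return None
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (pos.size * neg.size)


def xcorr_bruteforce(a, b, fs):
    """Normalized cross-correlation peak/lag by looping over every lag."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    L = a.size
    a0, b0 = a - a.mean(), b - b.mean()
    sa, sb = a0.std(), b0.std()
    if sa == 0 or sb == 0:
        return 0.0, 0.0
    best_r, best_lag = -np.inf, 0
    for lag in range(-(L - 1), L):
        # r(lag) = sum_t a0[t + lag] * b0[t] over the overlap
        s = 0.0
        for tt in range(L):
            ta = tt + lag
            if 0 <= ta < L:
                s += a0[ta] * b0[tt]
        r = s / (L * sa * sb)
        if r > best_r + 1e-12 or (abs(r - best_r) <= 1e-12
                                  and abs(lag) < abs(best_lag)):
            best_r, best_lag = r, lag
    return float(best_r), float(best_lag / fs)


def window_count_bruteforce(n_samples, length, step):
    """Count valid window start indices by enumeration."""
    count = 0
    start = 0
    while start + length <= n_samples:
        count += 1
        start += step
    return count


def cnn_param_count(conv, dense, n_classes, input_samples, input_channels):
    """Closed-form trainable-parameter total, written independently."""
    total = 0
    length, ch = input_samples, input_channels
    for kernel, filters, pool in conv:
        total += kernel * ch * filters + filters
        length //= pool
        ch = filters
    dim = length * ch
    for width in dense:
        total += dim * width + width
        dim = width
    total += dim * n_classes + n_classes
    return total
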