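"""Independent reference implementations used only by the tests.

Each oracle is a deliberately naive per-sample / closed-form computation,
kept free of the package's vectorised code paths so that agreement is a
genuine cross-check.
"""

from __future__ import annotations

import math

import numpy as np


def ewma_reference(x, alpha):
    """y[n] = alpha*y[n-1] + (1-alpha)*x[n], y[0] = x[0], plain loop."""
    y = [float(x[0])]
    for v in x[1:]:
        y.append(alpha * y[-1] + (1 - alpha) * float(v))
    return np.array(y)


def brute_force_detect(env, fs, threshold, min_duration, merge_gap=0.0, t0=0.0):
    """Per-sample double-threshold scan; returns (onset, offset) second pairs."""
    runs = []
    start = None
    for i, v in enumerate(env):
        if v > threshold:
            if start is None:
                start = i
        else:
            if start is not None:
                runs.append((start, i))
                start = None
    if start is not None:
        runs.append((start, len(env)))
    if merge_gap > 0:
        merged = []
        for s, e in runs:
            if merged and (s - merged[-1][1]) <= merge_gap * fs + 1e-9:
                merged[-1] = (merged[-1][0], e)
            else:
                merged.append((s, e))
        runs = merged
    kept = [(s, e) for s, e in runs if (e - s) + 1e-9 >= min_duration * fs]
    return [(t0 + s / fs, t0 + e / fs) for s, e in kept]


def trailing_mean_reference(x, w):
    """Naive trailing-window mean, NaN where no full window exists."""
    out = np.full(len(x), np.nan)
    for i in range(w - 1, len(x)):
        out[i] = sum(x[i - w + 1 : i + 1]) / w
    return out


def trigger_reference(ma, times, threshold, refractory):
    """Per-sample state machine for the reward rule."""
    triggers = []
    armed = True
    last = -math.inf
    for t, v in zip(times, ma):
        if not np.isfinite(v):
            continue
        if v > threshold:
            if armed and (t - last) >= refractory:
                triggers.append(t)
                last = t
                armed = False
        else:
            armed = True
    return triggers


def sequence_partition_reference(peaks, n_min, max_gap):
    """Brute-force partition into maximal close-spaced runs; keep >= n_min."""
    runs = []
    current = [0] if len(peaks) else []
    for i in range(1, len(peaks)):
        if peaks[i] - peaks[i - 1] <= max_gap:
            current.append(i)
        else:
            runs.append(current)
            current = [i]
    if current:
        runs.append(current)
    return [r for r in runs if len(r) >= n_min]


def greedy_pair_reference(burst_peaks, bite_peaks, max_lag):
    """Nearest free burst for each bite in time order; (bite_idx, burst_idx)."""
    used = set()
    pairs = []
    for i in sorted(range(len(bite_peaks)), key=lambda k: bite_peaks[k]):
        best, best_lag = None, math.inf
        for j in range(len(burst_peaks)):
            if j in used:
                continue
            lag = abs(burst_peaks[j] - bite_peaks[i])
            if lag < best_lag:
                best, best_lag = j, lag
        if best is not None and best_lag <= max_lag:
            used.add(best)
            pairs.append((i, best))
    return pairs


def pooled_t_reference(x, y):
    """Closed-form pooled-variance two-sample t and two-tailed p."""
    from scipy.stats import t as tdist

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * tdist.sf(abs(t), df)
    return t, df, p


def ols_reference(u, e):
    """Normal-equation solution of e = c*u + d."""
    u = np.asarray(u, dtype=float)
    e = np.asarray(e, dtype=float)
    X = np.column_stack([u, np.ones_like(u)])
    coef = np.linalg.solve(X.T @ X, X.T @ e)
    return float(coef[0]), float(coef[1])
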