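"""Independent brute-force reference implementations used only by tests.

Everything here is written as literal, per-element Python following the
textual rules of each procedure — no vectorization, no shared code with the
package — so that agreement with the package constitutes a genuine
cross-check.
"""

from __future__ import annotations

import math

import numpy as np


def hecht_oracle(vmu, threshold=5.0, window=20, window_spikes=2):
    """Literal three-condition vote per minute; 1 = non-wear."""
    n = len(vmu)
    out = []
    for m in range(n):
        c1 = vmu[m] > threshold
        following = [v for v in vmu[m + 1 : m + 1 + window] if v > threshold]
        c2 = len(following) >= window_spikes
        preceding = [v for v in vmu[max(0, m - window) : m] if v > threshold]
        c3 = len(preceding) >= window_spikes
        wear = (int(c1) + int(c2) + int(c3)) >= 2
        out.append(0 if wear else 1)
    return np.array(out, dtype=np.uint8)


def troiano_oracle(a, min_interval=60, spikes_allowed=2, spike_lower=0.0,
                   spike_upper=100.0):
    """Greedy forward run scan with cumulative spike accounting."""
    n = len(a)
    out = [0] * n
    i = 0
    while i < n:
        if a[i] > spike_lower:
            i += 1
            continue
        j, spikes = i, 0
        while j < n:
            if a[j] <= spike_lower:
                j += 1
            elif spike_lower < a[j] < spike_upper and spikes < spikes_allowed:
                spikes += 1
                j += 1
            else:
                break
        if j - i >= min_interval:
            for m in range(i, j):
                out[m] = 1
        if j < n and a[j] > spike_lower:
            i = j + 1
        else:
            i = j
    return np.array(out, dtype=np.uint8)


def choi_oracle(a, min_interval=90, interval_spikes=2, window=30, window_spikes=0):
    """Single-pass zero-run scan with flank-checked burst absorption."""
    n = len(a)
    nonzero = [x > 0 for x in a]
    out = [0] * n

    def flank_ok(burst_start, burst_end):
        up = sum(nonzero[max(0, burst_start - window) : burst_start])
        down = sum(nonzero[burst_end : min(n, burst_end + window)])
        return up <= window_spikes and down <= window_spikes

    i = 0
    while i < n:
        if nonzero[i]:
            i += 1
            continue
        j = i
        while j < n:
            if not nonzero[j]:
                j += 1
                continue
            b = j
            while b < n and nonzero[b]:
                b += 1
            if b - j <= interval_spikes and b < n and flank_ok(j, b):
                j = b
            else:
                break
        if j - i >= min_interval:
            for m in range(i, j):
                out[m] = 1
        i = max(j, i + 1)
    return np.array(out, dtype=np.uint8)


def zero_run_oracle(a, min_interval):
    """Plain zero-run thresholding: no spikes tolerated at all."""
    n = len(a)
    out = [0] * n
    i = 0
    while i < n:
        if a[i] != 0:
            i += 1
            continue
        j = i
        while j < n and a[j] == 0:
            j += 1
        if j - i >= min_interval:
            for m in range(i, j):
                out[m] = 1
        i = j
    return np.array(out, dtype=np.uint8)


def dtw_banded(a, b, band):
    """Exact DTW distance (sum of squared local costs) by full dynamic
    programming, with warping paths restricted to a Sakoe-Chiba band."""
    n, m = len(a), len(b)
    inf = math.inf
    d = [[inf] * (m + 1) for _ in range(n + 1)]
    d[0][0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if abs(i - j) > band:
                continue
            cost = (a[i - 1] - b[j - 1]) ** 2
            d[i][j] = cost + min(d[i - 1][j], d[i][j - 1], d[i - 1][j - 1])
    return d[n][m]


def window_stats_loop(data, start_sample, n_samples):
    """Two-pass per-axis population std and range in mg, by explicit loops."""
    stds, ranges = [], []
    for ax in range(3):
        xs = [float(data[i][ax]) for i in range(start_sample, start_sample + n_samples)]
        mean = sum(xs) / len(xs)
        var = sum((x - mean) ** 2 for x in xs) / len(xs)
        stds.append(math.sqrt(var) * 1000.0)
        ranges.append((max(xs) - min(xs)) * 1000.0)
    return np.array(stds), np.array(ranges)


def confusion_loop(truth, predicted):
    """Per-minute confusion tallies by explicit comparison."""
    tp = tn = fp = fn = 0
    for t, p in zip(truth, predicted):
        if t == 1 and p == 1:
            tp += 1
        elif t == 0 and p == 0:
            tn += 1
        elif t == 0 and p == 1:
            fp += 1
        else:
            fn += 1
    return tp, tn, fp, fn
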