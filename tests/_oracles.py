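"""Independent brute-force oracles used to validate the fast implementations.

These deliberately use naive O(n^2) counting, explicit run merging and
dense grid searches; they share no code with the package internals.
"""
from __future__ import annotations

import math

import numpy as np


def brute_qualified(times, M, T):
    """O(n^2) neighbor counting: photon i qualified iff >= M photons of
    `times` (incl. itself) lie within [t_i - T/2, t_i + T/2]."""
    times = list(times)
    out = []
    for t in times:
        count = 0
        for u in times:
            if t - T / 2.0 <= u <= t + T / 2.0:
                count += 1
        out.append(count >= M)
    return out


def _runs_intervals(times, flags):
    """Intervals (first_t, last_t) of maximal qualified runs, with run
    photon counts."""
    intervals = []
    start = None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        if not f and start is not None:
            intervals.append((times[start], times[i - 1], i - start))
            start = None
    if start is not None:
        intervals.append((times[start], times[-1], len(times) - start))
    return intervals


def brute_count_in_window(t, times, T):
    """O(n) scan: photons of `times` within [t - T/2, t + T/2]."""
    count = 0
    for u in times:
        if t - T / 2.0 <= u <= t + T / 2.0:
            count += 1
    return count


def brute_burst_search(ts, exc, M, T, L, mode):
    """Reference burst search. Returns a list of dicts with start, end and
    the photon index range [i0, i1) of each burst in the full stream.

    all-photon: photon qualified iff >= M full-stream photons in window.
    dual-color: photon qualified iff >= M donor-excitation photons AND
    >= M acceptor-excitation photons in its window.
    """
    ts = list(ts)
    exc = list(exc)
    if mode == "all-photon":
        flags = brute_qualified(ts, M, T)
    else:
        dex = [t for t, x in zip(ts, exc) if x == 0]
        aex = [t for t, x in zip(ts, exc) if x == 1]
        flags = [brute_count_in_window(t, dex, T) >= M
                 and brute_count_in_window(t, aex, T) >= M for t in ts]
    intervals = [(s, e) for (s, e, n) in _runs_intervals(ts, flags)
                 if n >= L]
    bursts = []
    for (s, e) in intervals:
        idx = [i for i, t in enumerate(ts) if s <= t <= e]
        if len(idx) >= L:
            bursts.append({"start": s, "end": e,
                           "i0": idx[0], "i1": idx[-1] + 1})
    return bursts


def brute_counts(ts, exc, ch, burst):
    """Tally (excitation, channel) counts for a brute-force burst."""
    keys = {(0, 0): "n_DexDem", (0, 1): "n_DexAem",
            (1, 0): "n_AexDem", (1, 1): "n_AexAem"}
    counts = {v: 0 for v in keys.values()}
    for i in range(burst["i0"], burst["i1"]):
        counts[keys[(exc[i], ch[i])]] += 1
    return counts


def binomial_tail_gt(m, p, threshold):
    """P[Binomial(m, p) > threshold] by direct summation."""
    total = 0.0
    for k in range(m + 1):
        if k > threshold:
            total += math.comb(m, k) * p ** k * (1 - p) ** (m - k)
    return total


def grid_search_A(t_used, D1, D2, target_D, step=1e-3):
    """Dense grid search for the mixture fraction whose model log-slope
    matches target_D; independent of the package's bisection solver."""
    best_a, best_err = 0.0, float("inf")
    a = 0.0
    tc = t_used - np.mean(t_used)
    sxx = float(np.dot(tc, tc))
    while a <= 1.0 + 1e-12:
        y = np.log(a * D1 * np.exp(-D1 * t_used)
                   + (1 - a) * D2 * np.exp(-D2 * t_used))
        slope = float(np.dot(tc, y - y.mean()) / sxx)
        err = abs(-slope - target_D)
        if err < best_err:
            best_a, best_err = a, err
        a += step
    return best_a


def random_test_stream(rng, max_photons=2000):
    """A random photon stream with background plus a few dense clusters,
    for oracle-equivalence testing."""
    duration_us = 500_000
    n_bg = int(rng.integers(100, 700))
    ts = [rng.uniform(0, duration_us) for _ in range(n_bg)]
    n_clusters = int(rng.integers(1, 8))
    for _ in range(n_clusters):
        t0 = rng.uniform(0, duration_us)
        width = rng.uniform(300, 3000)
        size = int(rng.integers(30, 200))
        ts.extend(t0 + rng.random(size) * width)
    ts = np.sort(np.asarray(ts[:max_photons], dtype=float)).astype(np.int64)
    ch = rng.integers(0, 2, size=ts.size).astype(np.uint8)
    return ts, ch


def brute_qualified_matrix(times, M, T):
    """Same O(n^2) qualification as brute_qualified, via an explicit
    all-pairs |t_i - t_j| matrix (faster, identical semantics)."""
    t = np.asarray(times, dtype=np.float64)
    within = np.abs(t[:, None] - t[None, :]) <= T / 2.0
    return (within.sum(axis=1) >= M).tolist()


def brute_burst_search_matrix(ts, exc, M, T, L, mode):
    """brute_burst_search with all-pairs matrix counting (same semantics)."""
    ts = list(ts)
    exc = list(exc)
    t_arr = np.asarray(ts, dtype=np.float64)
    if mode == "all-photon":
        flags = brute_qualified_matrix(ts, M, T)
    else:
        x = np.asarray(exc)
        within = np.abs(t_arr[:, None] - t_arr[None, :]) <= T / 2.0
        n_dex = (within & (x[None, :] == 0)).sum(axis=1)
        n_aex = (within & (x[None, :] == 1)).sum(axis=1)
        flags = ((n_dex >= M) & (n_aex >= M)).tolist()
    intervals = [(s, e) for (s, e, n) in _runs_intervals(ts, flags)
                 if n >= L]
    bursts = []
    for (s, e) in intervals:
        idx = np.flatnonzero((t_arr >= s) & (t_arr <= e))
        if idx.size >= L:
            bursts.append({"start": s, "end": e,
                           "i0": int(idx[0]), "i1": int(idx[-1]) + 1})
    return bursts
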