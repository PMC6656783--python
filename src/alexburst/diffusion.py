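"""Burst-duration diffusion analysis.

A molecule's transit time through the confocal volume scales inversely with
its diffusion coefficient, so the tail of the burst-duration histogram is
approximately exponential,

    P(t; D) = N * D * exp(-D * t),

where D (reciprocal milliseconds) is a *relative* diffusion constant (it
absorbs the excitation-volume geometry) and N a proportionality constant
that never needs estimating: on the log scale the tail is linear with slope
-D, so ordinary least-squares regression of log(m_i) on the bin centers
over a tail window (defaults 2-8 ms) yields the estimator D-hat and a 95%
confidence interval from the regression slope standard error.

For a mixture of a slow ribosome-bound species (rate D1) and a fast free
species (rate D2), the tail is

    P(t; D1, D2, A) = N * (A D1 exp(-D1 t) + (1-A) D2 exp(-D2 t)),

no longer log-linear. The bound fraction A is estimated by matching slopes:
find A such that the same OLS slope functional applied to
log P(t_i; D1, D2, A) over the same bins equals the measured slope. The
constant N cancels under the log, and the model slope is strictly monotone
in A between -D2 (A=0) and -D1 (A=1), so bisection on [0, 1] is exact.

A Stokes-Einstein consistency check relates diffusion-constant ratios to
molecular-mass ratios of free versus ribosome-bound complexes via
D proportional to m^(-1/3) for a spherical particle.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import brentq

from .burst_search import BurstSet

__all__ = [
    "DurationHistogram", "DiffusionEstimate", "BoundFractionEstimate",
    "burst_duration_histogram", "duration_histogram", "estimate_D",
    "mixture_tail", "estimate_bound_fraction", "per_state_bound_fraction",
    "PerStateResult", "stokes_einstein_ratio",
]


@dataclass
class DurationHistogram:
    """Histogram of burst durations with bin size ``delta_us``: bin i is
    centered at t = i*delta and counts durations in [i*delta - delta/2,
    i*delta + delta/2)."""

    delta_us: float
    m: np.ndarray       # counts per bin, index 0 .. i_max
    n_total: int

    @property
    def t_ms(self) -> np.ndarray:
        return np.arange(self.m.size) * self.delta_us / 1000.0


@dataclass
class DiffusionEstimate:
    D_hat: float            # 1/ms
    ci95: tuple             # (low, high)
    stderr: float
    t1_ms: float
    t2_ms: float
    k: int                  # number of bins used
    t_used_ms: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {"D_hat": self.D_hat, "ci95": list(self.ci95),
                "stderr": self.stderr, "t1_ms": self.t1_ms,
                "t2_ms": self.t2_ms, "k": self.k}


@dataclass
class BoundFractionEstimate:
    A_hat: float
    D1: float
    D2: float
    D_hat_measured: float
    clamped: bool = False
    k: int = 0

    def to_dict(self) -> dict:
        return {"A_hat": self.A_hat, "D1": self.D1, "D2": self.D2,
                "D_hat_measured": self.D_hat_measured,
                "clamped": self.clamped, "k": self.k}


def duration_histogram(durations_ms, delta_us: float = 200.0) -> DurationHistogram:
    """Bin a sequence of durations (ms). ``delta_us`` must lie in the sane
    instrument range 50-1000 us; counts conserve the number of inputs."""
    if not 50.0 <= delta_us <= 1000.0:
        raise ValueError("delta_us must be within 50-1000 us")
    d = np.asarray(durations_ms, dtype=float)
    if d.size == 0:
        return DurationHistogram(delta_us, np.zeros(0), 0)
    delta_ms = delta_us / 1000.0
    idx = np.floor(d / delta_ms + 0.5).astype(np.int64)
    m = np.bincount(idx)
    return DurationHistogram(delta_us, m.astype(float), int(d.size))


def burst_duration_histogram(bursts: BurstSet,
                             delta_us: float = 200.0) -> DurationHistogram:
    return duration_histogram(bursts.df["duration_ms"].to_numpy(), delta_us)


def _ols_slope(t: np.ndarray, y: np.ndarray) -> float:
    tc = t - t.mean()
    return float(np.dot(tc, y - y.mean()) / np.dot(tc, tc))


def estimate_D(hist: DurationHistogram, t1_ms: float = 2.0,
               t2_ms: float = 8.0) -> DiffusionEstimate:
    """OLS log-slope estimator of the relative diffusion constant.

    Fits log(m_i) vs t_i over bins with t1 <= t_i <= t2; zero-count bins
    are dropped (log undefined). Needs at least 3 usable bins. The 95% CI
    is Student-t based on the regression slope standard error.
    """
    if t1_ms >= t2_ms:
        raise ValueError("require t1 < t2")
    t = hist.t_ms
    mask = (t >= t1_ms) & (t <= t2_ms) & (hist.m > 0)
    k = int(mask.sum())
    if k < 3:
        raise ValueError(f"only {k} nonzero bins in [{t1_ms}, {t2_ms}] ms; "
                         "need >= 3")
    tt = t[mask]
    yy = np.log(hist.m[mask])
    slope = _ols_slope(tt, yy)
    d_hat = -slope
    # the variance of log-counts grows along the tail (smaller counts), so
    # the slope standard error uses the HC3 sandwich form rather than the
    # homoscedastic residual variance
    tc = tt - tt.mean()
    sxx = float(np.dot(tc, tc))
    resid = yy - (yy.mean() + slope * tc)
    lev = 1.0 / k + tc ** 2 / sxx
    stderr = float(np.sqrt(np.sum((tc / sxx) ** 2
                                  * (resid / (1.0 - lev)) ** 2)))
    tq = stats.t.ppf(0.975, k - 2) if k > 2 else np.inf
    ci = (d_hat - tq * stderr, d_hat + tq * stderr)
    return DiffusionEstimate(float(d_hat), ci, stderr, t1_ms, t2_ms, k, tt)


def mixture_tail(t_ms, D1: float, D2: float, A: float, N: float = 1.0):
    """Two-component exponential tail: N (A D1 e^{-D1 t} + (1-A) D2 e^{-D2 t})."""
    t = np.asarray(t_ms, dtype=float)
    out = N * (A * D1 * np.exp(-D1 * t) + (1.0 - A) * D2 * np.exp(-D2 * t))
    return float(out) if np.ndim(t_ms) == 0 else out


def _model_slope(t_used: np.ndarray, D1: float, D2: float, A: float) -> float:
    return _ols_slope(t_used, np.log(mixture_tail(t_used, D1, D2, A)))


def estimate_bound_fraction(hist: DurationHistogram, D1_hat: float,
                            D2_hat: float, t1_ms: float = 2.0,
                            t2_ms: float = 8.0) -> BoundFractionEstimate:
    """Estimate the bound fraction A by slope matching.

    Measures the log-slope of ``hist`` over [t1, t2] and solves for the A
    whose two-component model tail has the same OLS slope over the same
    bins. Outside the bracketed slope range, A-hat is clamped to the
    nearest endpoint and flagged.
    """
    if D1_hat <= 0 or D2_hat <= 0:
        raise ValueError("diffusion rates must be positive")
    if D1_hat == D2_hat:
        raise ValueError("D1 and D2 must differ")
    meas = estimate_D(hist, t1_ms, t2_ms)
    t_used = meas.t_used_ms

    def g(a: float) -> float:
        return -_model_slope(t_used, D1_hat, D2_hat, a) - meas.D_hat

    g0, g1 = g(0.0), g(1.0)
    if g0 == 0.0:
        a_hat, clamped = 0.0, False
    elif g1 == 0.0:
        a_hat, clamped = 1.0, False
    elif g0 * g1 > 0:
        # measured slope outside [slope(A=0), slope(A=1)]
        a_hat = 0.0 if abs(g0) < abs(g1) else 1.0
        clamped = True
    else:
        a_hat = float(brentq(g, 0.0, 1.0, xtol=1e-12, rtol=1e-14))
        clamped = False
    return BoundFractionEstimate(a_hat, D1_hat, D2_hat, meas.D_hat,
                                 clamped, meas.k)


@dataclass
class PerStateResult:
    n_bursts: int
    estimate: BoundFractionEstimate | None
    flagged: bool = False  # True when the subset was too small to estimate


def per_state_bound_fraction(bursts: BurstSet, state_windows: dict,
                             D1: float, D2: float, delta_us: float = 200.0,
                             t1_ms: float = 2.0, t2_ms: float = 8.0,
                             min_bursts: int = 1000) -> dict:
    """Bound fraction per conformational state.

    ``state_windows`` maps state name -> (E*_low, E*_high); windows must be
    disjoint. Subsets smaller than ``min_bursts`` are flagged, not
    estimated.
    """
    items = list(state_windows.items())
    for (na, (a0, a1)) in items:
        if a0 >= a1:
            raise ValueError(f"inverted window for state {na!r}")
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            (_, (a0, a1)), (_, (b0, b1)) = items[i], items[j]
            if max(a0, b0) < min(a1, b1):
                raise ValueError("state windows must be disjoint")
    e = bursts.df["E_star"].to_numpy()
    out = {}
    for name, (lo, hi) in items:
        sub = bursts.df[(e >= lo) & (e <= hi)]
        n = len(sub)
        if n < min_bursts:
            out[name] = PerStateResult(n, None, flagged=True)
            continue
        hist = duration_histogram(sub["duration_ms"].to_numpy(), delta_us)
        est = estimate_bound_fraction(hist, D1, D2, t1_ms, t2_ms)
        out[name] = PerStateResult(n, est)
    return out


def stokes_einstein_ratio(mass1_kda: float, mass2_kda: float) -> float:
    """Predicted D1/D2 ratio for spherical particles of masses m1 < m2:
    D scales as m^(-1/3), so D(mass1)/D(mass2) = (mass2/mass1)^(1/3)."""
    if mass1_kda <= 0 or mass2_kda <= 0:
        raise ValueError("masses must be positive")
    return float((mass2_kda / mass1_kda) ** (1.0 / 3.0))
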