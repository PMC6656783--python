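"""Gaussian-mixture decomposition of apparent-FRET histograms.

One-dimensional E* histograms of donor-acceptor bursts are fitted with a
sum of 1-3 Gaussian components by weighted least squares on the binned
histogram. Component means are the apparent FRET values of conformational
states; component areas, normalized to one, are the state abundances.
Standard deviations are constrained to a small interval (defaults
[0.015, 0.10] in E* units, bracketing the shot-noise width sqrt(E(1-E)/N)
of bursts of a few hundred photons across the E* range, the regime
calibrated in practice with static double-labeled DNA standards); this
keeps the decomposition identifiable.

Model order is chosen as the minimum number of components that fits the
data: starting from one component, a further component is added only while
it still improves the reduced chi-square by more than a relative threshold
(default 10%) and yields no vanishing (< 1%) component weight.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = ["MixtureComponent", "MixtureResult", "fit_mixture",
           "select_model", "state_populations"]

STATE_LABELS = ("open", "intermediate", "closed")  # by ascending E*


@dataclass(frozen=True)
class MixtureComponent:
    mean: float     # apparent FRET of the state
    sigma: float    # Gaussian width, E* units
    weight: float   # normalized area, sums to 1 over a result


@dataclass
class MixtureResult:
    components: list
    n_components: int
    reduced_chisq: float
    success: bool = True
    goodness_by_k: dict = field(default_factory=dict)
    bin_width: float = 0.02

    @property
    def means(self) -> np.ndarray:
        return np.array([c.mean for c in self.components])

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([c.sigma for c in self.components])

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "reduced_chisq": self.reduced_chisq,
            "components": [
                {"mean": c.mean, "sigma": c.sigma, "weight": c.weight}
                for c in self.components],
            "goodness_by_k": {str(k): v
                              for k, v in self.goodness_by_k.items()},
        }


def _histogram(e_values: np.ndarray, bin_width: float):
    nbins = max(int(round(1.0 / bin_width)), 2)
    edges = np.linspace(0.0, 1.0, nbins + 1)
    counts, _ = np.histogram(e_values, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return counts.astype(float), centers


def _gauss_sum(x, params, k):
    y = np.zeros_like(x)
    for j in range(k):
        amp, mu, sig = params[3 * j: 3 * j + 3]
        y = y + amp * np.exp(-0.5 * ((x - mu) / sig) ** 2)
    return y


def _initial_means(e_values, counts, centers, k):
    """Deterministic multi-start grid: histogram peaks, sample quantiles,
    and equispaced positions."""
    starts = []
    # local maxima of the (lightly smoothed) histogram, k largest
    sm = np.convolve(counts, np.ones(3) / 3.0, mode="same")
    interior = np.arange(1, len(sm) - 1)
    peaks = interior[(sm[interior] >= sm[interior - 1])
                     & (sm[interior] >= sm[interior + 1])]
    if peaks.size >= k:
        top = peaks[np.argsort(sm[peaks])[::-1][:k]]
        starts.append(np.sort(centers[top]))
    qs = np.quantile(e_values, (np.arange(k) + 1) / (k + 1.0))
    starts.append(np.asarray(qs, dtype=float))
    lo, hi = float(np.min(e_values)), float(np.max(e_values))
    starts.append(np.linspace(lo, hi, k + 2)[1:-1])
    # deduplicate
    uniq = []
    for s in starts:
        if not any(np.allclose(s, u, atol=1e-3) for u in uniq):
            uniq.append(s)
    return uniq


def fit_mixture(e_values, k: int, sigma_bounds=(0.015, 0.10),
                bin_width: float = 0.02) -> MixtureResult:
    """Weighted least-squares fit of a k-component Gaussian sum to the
    binned E* histogram.

    Requires at least 50 values and 1 <= k <= 3. Weights are 1/sqrt(count)
    (Poisson); component weights are areas (amplitude x sigma) normalized
    to one; components are reported sorted by ascending mean.
    """
    e_values = np.asarray(e_values, dtype=float)
    e_values = e_values[np.isfinite(e_values)]
    if e_values.size < 50:
        raise ValueError("need at least 50 E* values")
    if not 1 <= k <= 3:
        raise ValueError("k must be 1, 2 or 3")
    sig_lo, sig_hi = sigma_bounds
    if not 0 < sig_lo <= sig_hi:
        raise ValueError("invalid sigma_bounds")
    if np.ptp(e_values) < 1e-12:
        raise ValueError("degenerate input: all E* values identical")

    counts, centers = _histogram(np.clip(e_values, 0.0, 1.0), bin_width)
    w = 1.0 / np.sqrt(np.maximum(counts, 1.0))
    amp0 = max(counts.max(), 1.0)
    sig0 = 0.5 * (sig_lo + sig_hi)

    def residuals(p):
        return (counts - _gauss_sum(centers, p, k)) * w

    lower = np.tile([0.0, 0.0, sig_lo], k)
    upper = np.tile([np.inf, 1.0, sig_hi], k)
    best = None
    for mus in _initial_means(e_values, counts, centers, k):
        p0 = np.empty(3 * k)
        for j in range(k):
            p0[3 * j: 3 * j + 3] = (amp0 / k, float(mus[j]), sig0)
        try:
            sol = least_squares(residuals, p0, bounds=(lower, upper),
                                method="trf", x_scale="jac", max_nfev=4000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return MixtureResult([], k, float("inf"), success=False,
                             bin_width=bin_width)

    p = best.x
    dof = max(len(counts) - 3 * k, 1)
    red_chisq = float(2 * best.cost / dof)
    comps = []
    areas = np.array([p[3 * j] * p[3 * j + 2] for j in range(k)])
    total = areas.sum()
    if total <= 0:
        return MixtureResult([], k, red_chisq, success=False,
                             bin_width=bin_width)
    for j in np.argsort([p[3 * j + 1] for j in range(k)]):
        comps.append(MixtureComponent(float(p[3 * j + 1]),
                                      float(p[3 * j + 2]),
                                      float(areas[j] / total)))
    return MixtureResult(comps, k, red_chisq, success=True,
                         bin_width=bin_width)


def select_model(e_values, sigma_bounds=(0.015, 0.10),
                 criterion_threshold: float = 0.10,
                 bin_width: float = 0.02, k_max: int = 3,
                 adequate_chisq: float = 1.5) -> MixtureResult:
    """Fit k = 1..k_max components and return the minimal adequate model.

    A model already consistent with the data (reduced chi-square at or
    below ``adequate_chisq``) is never extended — extra components would
    only fit counting noise. Otherwise a further component is accepted
    only if it improves the reduced chi-square by more than
    ``criterion_threshold`` (relative) and the richer fit is
    non-degenerate (no component weight below 1%).
    """
    results = {}
    for k in range(1, k_max + 1):
        results[k] = fit_mixture(e_values, k, sigma_bounds, bin_width)
    goodness = {k: r.reduced_chisq for k, r in results.items()}
    chosen = 1
    for k in range(1, k_max):
        cur, nxt = results[k], results[k + 1]
        if cur.success and cur.reduced_chisq <= adequate_chisq:
            break
        if not nxt.success or np.any(nxt.weights < 0.01):
            break
        improvement = (cur.reduced_chisq - nxt.reduced_chisq) \
            / max(cur.reduced_chisq, 1e-300)
        if improvement <= criterion_threshold:
            break
        chosen = k + 1
    result = results[chosen]
    result.goodness_by_k = goodness
    return result


def state_populations(result: MixtureResult) -> dict:
    """Percentages per conformational state, labelled by ascending mean.

    Three components map onto (open, intermediate, closed); with fewer
    components the states are reported by their mean E* only.
    """
    if not result.components:
        raise ValueError("cannot label an unsuccessful fit")
    weights = result.weights
    pct = 100.0 * weights / weights.sum()
    if len(result.components) == len(STATE_LABELS):
        labels = STATE_LABELS
    else:
        labels = tuple(f"E*={c.mean:.2f}" for c in result.components)
    return dict(zip(labels, pct.tolist()))
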