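"""Binding-kinetics fits and arithmetic.

Titration data (ligand concentration vs bound fraction) are fitted with the
hyperbolic binding isotherm f(c) = c / (Kd + c) (free ligand approximately
equal to total, valid when the labeled species is in trace amounts; a
quadratic ligand-depletion model is available behind a flag). Dissociation
time courses are fitted with f(t) = f0 exp(-koff t). The standard kinetic
chain then follows:

    kon  = koff / Kd          (koff converted from 1/min to 1/s)
    tau  = 1 / (kon * c)      mean association time at concentration c

Units: Kd in molar, koff per minute (stored as measured), kon per molar per
second, tau in seconds.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

__all__ = ["FitResult", "KineticsResult", "fit_kd", "fit_dissociation_rate",
           "association_rate", "mean_association_time", "kinetics_chain"]


@dataclass
class FitResult:
    value: float
    stderr: float
    ci95: tuple
    params: dict
    residuals: np.ndarray
    flag: str | None = None


@dataclass
class KineticsResult:
    """Chained kinetic quantities; kon = (koff/60)/kd and
    tau_assoc = 1/(kon * conc) hold by construction."""

    kd: float               # M
    koff: float             # 1/min
    kon: float              # 1/(M s)
    conc: float             # M, concentration at which tau is evaluated
    tau_assoc: float        # s

    def to_dict(self) -> dict:
        return {"kd_M": self.kd, "koff_per_min": self.koff,
                "kon_per_M_s": self.kon, "conc_M": self.conc,
                "tau_assoc_s": self.tau_assoc}


def _ci(value: float, stderr: float, dof: int) -> tuple:
    tq = stats.t.ppf(0.975, max(dof, 1))
    return (value - tq * stderr, value + tq * stderr)


def _binomial_sigma(f: np.ndarray, n) -> np.ndarray:
    return np.sqrt(np.maximum(f * (1 - f), 1e-4) / np.asarray(n, dtype=float))


def fit_kd(concentrations, bound_fractions, n_per_point=None,
           total_labeled: float | None = None) -> FitResult:
    """Fit the dissociation constant from a titration.

    Needs >= 4 points; warns when the data do not span half-saturation
    (the CI is then wide). If per-point molecule counts are given the fit
    is weighted by binomial errors. ``total_labeled`` (molar) switches to
    the quadratic depletion model.
    """
    c = np.asarray(concentrations, dtype=float)
    f = np.asarray(bound_fractions, dtype=float)
    if c.size < 4:
        raise ValueError("need at least 4 titration points")
    if np.any(c < 0):
        raise ValueError("concentrations must be >= 0")
    flag = None
    if f.max() < 0.5 or f.min() > 0.5:
        warnings.warn("titration does not span half-saturation; "
                      "Kd confidence interval will be wide")
        flag = "non-spanning"

    if total_labeled is None:
        def model(cc, kd):
            return cc / (kd + cc)
    else:
        p_tot = float(total_labeled)

        def model(cc, kd):
            b = cc + p_tot + kd
            return (b - np.sqrt(b * b - 4.0 * p_tot * cc)) / (2.0 * p_tot)

    # initial guess: concentration nearest half-saturation
    kd0 = float(c[np.argmin(np.abs(f - 0.5))]) or float(np.median(c[c > 0]))
    sigma = _binomial_sigma(f, n_per_point) if n_per_point is not None else None
    popt, pcov = curve_fit(model, c, f, p0=[kd0], sigma=sigma,
                           absolute_sigma=n_per_point is not None,
                           bounds=(1e-15, np.inf), maxfev=10000)
    kd = float(popt[0])
    stderr = float(np.sqrt(pcov[0, 0]))
    resid = f - model(c, kd)
    return FitResult(kd, stderr, _ci(kd, stderr, c.size - 1),
                     {"kd": kd}, resid, flag)


def fit_dissociation_rate(times_min, bound_fractions,
                          n_per_point=None) -> FitResult:
    """Fit koff (per minute) from a dissociation time course
    f(t) = f0 exp(-koff t); increasing data yield koff = 0 with a flag."""
    t = np.asarray(times_min, dtype=float)
    f = np.asarray(bound_fractions, dtype=float)
    if t.size < 4:
        raise ValueError("need at least 4 time points")
    if np.any(t < 0):
        raise ValueError("times must be >= 0")

    def model(tt, f0, k):
        return f0 * np.exp(-k * tt)

    # log-linear initial guess on the positive part
    pos = f > 0
    if pos.sum() >= 2:
        slope = np.polyfit(t[pos], np.log(f[pos]), 1)[0]
        k0 = max(-slope, 0.0)
    else:
        k0 = 1.0
    sigma = _binomial_sigma(f, n_per_point) if n_per_point is not None else None
    popt, pcov = curve_fit(model, t, f, p0=[max(f.max(), 1e-3), k0],
                           sigma=sigma,
                           absolute_sigma=n_per_point is not None,
                           bounds=([0.0, 0.0], [np.inf, np.inf]),
                           maxfev=10000)
    f0, koff = float(popt[0]), float(popt[1])
    stderr = float(np.sqrt(pcov[1, 1]))
    flag = "nondecreasing-data" if koff < 1e-8 else None
    resid = f - model(t, f0, koff)
    return FitResult(koff, stderr, _ci(koff, stderr, t.size - 2),
                     {"f0": f0, "koff": koff}, resid, flag)


def association_rate(koff_per_min: float, kd_M: float) -> float:
    """kon = koff / Kd with koff converted to per second; 1/(M s)."""
    if koff_per_min < 0:
        raise ValueError("koff must be >= 0")
    if kd_M <= 0:
        raise ValueError("kd must be positive")
    return (koff_per_min / 60.0) / kd_M


def mean_association_time(kon_per_M_s: float, conc_M: float) -> float:
    """Mean waiting time to bind at ligand concentration c: 1/(kon c)."""
    if kon_per_M_s <= 0 or conc_M <= 0:
        raise ValueError("kon and concentration must be positive")
    return 1.0 / (kon_per_M_s * conc_M)


def kinetics_chain(kd_M: float, koff_per_min: float,
                   conc_M: float) -> KineticsResult:
    """Chain Kd and koff into kon and the mean association time at a
    stated ligand concentration."""
    kon = association_rate(koff_per_min, kd_M)
    tau = mean_association_time(kon, conc_M) if kon > 0 else float("inf")
    return KineticsResult(kd_M, koff_per_min, kon, conc_M, tau)
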