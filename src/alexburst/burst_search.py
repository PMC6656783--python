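"""Sliding-window burst detection and per-burst FRET observables.

A photon is *burst-qualified* when at least ``M`` photons of the tested
stream fall within a centered window of ``T`` microseconds around its
timestamp. Maximal runs of consecutive qualified photons with at least
``L`` photons become bursts. In ``all-photon`` mode the tested stream is
the full stream; in ``dual-color`` mode every photon must satisfy the M/T
criterion independently in the donor-excitation stream AND in the
acceptor-excitation stream (the intersection of the two qualified photon
sets), which selects molecules carrying both an active donor and an active
acceptor.

Per burst, photon counts are tallied by (excitation period, detection
channel) and converted to the two standard ALEX observables:

* apparent FRET efficiency ``E* = n_DexAem / (n_DexDem + n_DexAem)`` —
  sensitized acceptor emission normalized to all emission during donor
  excitation (uncorrected for leakage, direct excitation or gamma);
* stoichiometry ``S = (n_DexDem + n_DexAem) / (n_DexDem + n_DexAem +
  n_AexAem)`` — donor-excitation signal over the total, separating
  donor-only (S ~ 1), acceptor-only (S ~ 0) and doubly labeled molecules
  (intermediate S).

``n_AexDem`` photons (donor emission during acceptor excitation) are tallied
but enter neither observable.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as _io
from .photons import AEX, DEX, DONOR, ACCEPTOR, PhotonStream

__all__ = [
    "BurstSearchParams", "BurstSet", "burst_search", "threshold_bursts",
    "compute_es", "select_species", "es_histogram",
]


@dataclass(frozen=True)
class BurstSearchParams:
    """Sliding-window burst-search parameters (defaults as used throughout
    the analysis: L = 25, M = 15, T = 500 us, threshold 250 photons)."""

    L: int = 25
    M: int = 15
    T: float = 500.0
    min_total_photons: int = 250
    mode: str = "dual-color"  # or "all-photon"

    def __post_init__(self) -> None:
        if self.L < 1 or self.M < 1:
            raise ValueError("L and M must be >= 1")
        if self.T <= 0:
            raise ValueError("T must be positive")
        if self.mode not in ("dual-color", "all-photon"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class BurstSet:
    """An ordered, non-overlapping collection of detected bursts.

    The table ``df`` holds one row per burst with the canonical columns
    (start/end, per-stream counts, E*, S); ``provenance`` records how the
    set was produced (source, parameters, filters applied).
    """

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.df.empty and not len(self.df.columns):
            self.df = pd.DataFrame(columns=_io.BURST_COLUMNS)
        starts = self.df["start_us"].to_numpy()
        if starts.size and np.any(np.diff(starts) < 0):
            raise ValueError("bursts must be ordered by start_us")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def total_photons(self) -> np.ndarray:
        c = self.df
        return (c["n_DexDem"] + c["n_DexAem"] + c["n_AexDem"]
                + c["n_AexAem"]).to_numpy()

    def with_df(self, df: pd.DataFrame, **prov) -> "BurstSet":
        return BurstSet(df.reset_index(drop=True),
                        {**self.provenance, **prov})

    def to_csv(self, path) -> None:
        _io.write_burst_csv(self.df, path)

    @classmethod
    def from_csv(cls, path, **prov) -> "BurstSet":
        return cls(_io.read_burst_csv(path), prov)

    @classmethod
    def from_counts(cls, start_us, end_us, n_dd, n_da, n_ad, n_aa, **prov):
        """Build a set from raw interval/count arrays, deriving E* and S."""
        start_us = np.asarray(start_us, dtype=np.int64)
        end_us = np.asarray(end_us, dtype=np.int64)
        e, s = compute_es(n_dd, n_da, n_aa)
        df = pd.DataFrame({
            "burst_id": np.arange(start_us.size),
            "start_us": start_us,
            "end_us": end_us,
            "duration_ms": (end_us - start_us) / 1000.0,
            "n_DexDem": np.asarray(n_dd, dtype=np.int64),
            "n_DexAem": np.asarray(n_da, dtype=np.int64),
            "n_AexDem": np.asarray(n_ad, dtype=np.int64),
            "n_AexAem": np.asarray(n_aa, dtype=np.int64),
            "E_star": e,
            "S": s,
        })
        return cls(df, prov)


def compute_es(n_dex_dem, n_dex_aem, n_aex_aem):
    """Apparent FRET efficiency and stoichiometry from photon counts.

    Returns NaN where the respective denominator is zero (the quantity is
    undefined for that burst). Works element-wise on arrays.
    """
    n_dd = np.asarray(n_dex_dem, dtype=float)
    n_da = np.asarray(n_dex_aem, dtype=float)
    n_aa = np.asarray(n_aex_aem, dtype=float)
    dex = n_dd + n_da
    tot = dex + n_aa
    with np.errstate(invalid="ignore", divide="ignore"):
        e = np.where(dex > 0, n_da / np.where(dex > 0, dex, 1.0), np.nan)
        s = np.where(tot > 0, dex / np.where(tot > 0, tot, 1.0), np.nan)
    if np.ndim(n_dex_dem) == 0:
        return float(e), float(s)
    return e, s


# ------------------------------------------------------------------ search

def _qualified(times: np.ndarray, M: int, T: float) -> np.ndarray:
    """Boolean mask: photon i has >= M photons (incl. itself) of this stream
    in the closed window [t_i - T/2, t_i + T/2]."""
    lo = np.searchsorted(times, times - T / 2.0, side="left")
    hi = np.searchsorted(times, times + T / 2.0, side="right")
    return (hi - lo) >= M


def _runs(mask: np.ndarray):
    """(start, stop) index pairs of maximal True runs; stop is exclusive."""
    if mask.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    edges = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    stops = np.flatnonzero(edges == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        stops = np.r_[stops, mask.size]
    return np.column_stack([starts, stops])


def burst_search(stream: PhotonStream,
                 params: BurstSearchParams | None = None) -> BurstSet:
    """Detect bursts in a photon stream.

    Returns an empty set for an empty stream. The stream container enforces
    time ordering, so an unsorted input cannot be constructed.
    """
    if params is None:
        params = BurstSearchParams()
    ts = stream.timestamps_us
    prov = {"params": params, "n_photons": len(stream)}
    if ts.size == 0:
        return BurstSet(pd.DataFrame(columns=_io.BURST_COLUMNS), prov)

    exc = stream.excitation
    if params.mode == "all-photon":
        q = _qualified(ts, params.M, params.T)
        runs = _runs(q)
        keep = (runs[:, 1] - runs[:, 0]) >= params.L
        runs = runs[keep]
        intervals = np.column_stack([ts[runs[:, 0]], ts[runs[:, 1] - 1]]) \
            if len(runs) else np.empty((0, 2), dtype=np.int64)
    else:  # dual-color: every photon must satisfy M/T in BOTH streams
        q = np.ones(ts.size, dtype=bool)
        for phase in (DEX, AEX):
            sub = ts[exc == phase]
            lo = np.searchsorted(sub, ts - params.T / 2.0, side="left")
            hi = np.searchsorted(sub, ts + params.T / 2.0, side="right")
            q &= (hi - lo) >= params.M
        runs = _runs(q)
        keep = (runs[:, 1] - runs[:, 0]) >= params.L
        runs = runs[keep]
        intervals = np.column_stack([ts[runs[:, 0]], ts[runs[:, 1] - 1]]) \
            if len(runs) else np.empty((0, 2), dtype=np.int64)

    if len(intervals) == 0:
        return BurstSet(pd.DataFrame(columns=_io.BURST_COLUMNS), prov)

    # per-category interval tallies via binary search on category substreams
    ch = stream.channel
    cats = {
        "n_DexDem": (exc == DEX) & (ch == DONOR),
        "n_DexAem": (exc == DEX) & (ch == ACCEPTOR),
        "n_AexDem": (exc == AEX) & (ch == DONOR),
        "n_AexAem": (exc == AEX) & (ch == ACCEPTOR),
    }
    counts = {}
    for k, mask in cats.items():
        sub = ts[mask]
        counts[k] = (np.searchsorted(sub, intervals[:, 1], side="right")
                     - np.searchsorted(sub, intervals[:, 0], side="left"))
    total = sum(counts.values())
    keep = total >= params.L
    bs = BurstSet.from_counts(
        intervals[keep, 0], intervals[keep, 1],
        counts["n_DexDem"][keep], counts["n_DexAem"][keep],
        counts["n_AexDem"][keep], counts["n_AexAem"][keep], **prov)
    return bs


def threshold_bursts(bursts: BurstSet, min_total_photons: int = 250) -> BurstSet:
    """Keep bursts with strictly more than ``min_total_photons`` photons."""
    keep = bursts.total_photons > min_total_photons
    return bursts.with_df(bursts.df[keep],
                          threshold=min_total_photons)


def select_species(bursts: BurstSet, s_min: float, s_max: float) -> BurstSet:
    """Select the doubly labeled (donor-acceptor) sub-population by its
    intermediate stoichiometry, keeping bursts with s_min <= S <= s_max."""
    if not (0 <= s_min < s_max <= 1):
        raise ValueError("require 0 <= s_min < s_max <= 1")
    s = bursts.df["S"].to_numpy()
    keep = (s >= s_min) & (s <= s_max)
    return bursts.with_df(bursts.df[keep], s_window=(s_min, s_max))


def es_histogram(bursts: BurstSet, e_bins=None, s_bins=None):
    """2-D (E*, S) histogram. Returns (counts, e_edges, s_edges); counts sum
    to the number of bursts with both observables defined and in range."""
    if e_bins is None:
        e_bins = np.linspace(0, 1, 51)
    if s_bins is None:
        s_bins = np.linspace(0, 1, 51)
    e_bins = np.asarray(e_bins, dtype=float)
    s_bins = np.asarray(s_bins, dtype=float)
    for edges in (e_bins, s_bins):
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
    e = bursts.df["E_star"].to_numpy()
    s = bursts.df["S"].to_numpy()
    ok = np.isfinite(e) & np.isfinite(s)
    h, ee, se = np.histogram2d(e[ok], s[ok], bins=[e_bins, s_bins])
    return h, ee, se
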