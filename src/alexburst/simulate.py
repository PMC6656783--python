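"""Synthetic us-ALEX photon streams and burst tables.

The generator emulates the photon statistics the burst analysis assumes:
molecule transits start as a Poisson process in time, transit durations are
exponential with a species-specific rate D (reciprocal milliseconds, the
"relative diffusion constant" — faster diffusion means shorter transits),
photon emission during a transit is Poisson with a rectangular intensity
profile, donor-excitation photons of a donor-acceptor species are routed to
the acceptor channel with probability equal to the apparent FRET efficiency,
and a uniform Poisson background is added per channel. Excitation alternates
every 50 us and the excitation phase of every photon is a pure function of
its integer-microsecond timestamp.

Large fluorescent aggregates are emulated as short runs (6-12 by default)
of consecutive bright transits with apparent FRET above a threshold — the
signature the burst-correlation filter is designed to remove.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .burst_search import BurstSet, compute_es
from .photons import ACCEPTOR, DONOR, PhotonStream

__all__ = [
    "SimSpecies", "SimConfig", "simulate_photon_stream", "inject_aggregates",
    "simulate_measurement", "simulate_burst_table", "simulate_titration",
    "simulate_dissociation_timecourse",
]

_STOICH_CLASSES = ("donor-acceptor", "donor-only", "acceptor-only")


@dataclass(frozen=True)
class SimSpecies:
    """One molecular species in a simulated sample.

    Parameters
    ----------
    fret_e : float
        Apparent FRET efficiency in [0, 1] (probability that a
        donor-excitation photon is detected in the acceptor channel).
    stoich_class : str
        ``donor-acceptor``, ``donor-only`` or ``acceptor-only``.
    diffusion_rate_D : float
        Exponential rate of transit durations, reciprocal milliseconds.
    brightness_dex, brightness_aex : float
        Detected photons per millisecond during a transit, under donor and
        acceptor excitation periods respectively.
    fraction : float
        Molar fraction of this species; fractions sum to 1 over a config.
    """

    name: str
    fret_e: float
    stoich_class: str = "donor-acceptor"
    diffusion_rate_D: float = 1.10
    brightness_dex: float = 400.0
    brightness_aex: float = 300.0
    fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fret_e <= 1.0:
            raise ValueError("fret_e must be in [0, 1]")
        if self.stoich_class not in _STOICH_CLASSES:
            raise ValueError(f"stoich_class must be one of {_STOICH_CLASSES}")
        if self.diffusion_rate_D <= 0:
            raise ValueError("diffusion_rate_D must be positive")
        if self.brightness_dex < 0 or self.brightness_aex < 0:
            raise ValueError("brightness must be >= 0")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must be in [0, 1]")
        if self.stoich_class == "donor-only" and self.brightness_aex != 0:
            raise ValueError("donor-only species cannot emit under Aex")
        if self.stoich_class == "acceptor-only" and self.brightness_dex != 0:
            raise ValueError("acceptor-only species cannot emit under Dex")


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of a simulated measurement.

    ``transit_rate_per_s`` sets how often molecules enter the confocal
    volume; the default keeps the duty cycle low enough that transit
    overlap is rare. Background rates are photons per second per channel.
    """

    species: tuple
    duration_s: float = 10.0
    transit_rate_per_s: float = 50.0
    alternation_period_us: int = 50
    background_rate_donor: float = 1000.0
    background_rate_acceptor: float = 600.0
    aggregate_burst_runs: int = 0
    aggregate_run_length_range: tuple = (6, 12)
    aggregate_e_min: float = 0.9
    aggregate_brightness_factor: tuple = (2.0, 5.0)
    donor_leakage: float = 0.0
    direct_excitation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        if not self.species:
            raise ValueError("at least one species required")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.alternation_period_us <= 0:
            raise ValueError("alternation_period_us must be positive")
        if min(self.background_rate_donor, self.background_rate_acceptor) < 0:
            raise ValueError("background rates must be >= 0")
        if self.transit_rate_per_s <= 0:
            raise ValueError("transit_rate_per_s must be positive")
        total = sum(s.fraction for s in self.species)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"species fractions must sum to 1, got {total}")
        lo, hi = self.aggregate_run_length_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid aggregate_run_length_range")


def _default_rng(config: SimConfig, stream_id: int) -> np.random.Generator:
    # independent, reproducible sub-streams per purpose
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(stream_id,)))


def _emit_transit_photons(rng, starts_us, dur_us, b_dex, b_aex, fret_e,
                          period_us, donor_leakage, direct_excitation):
    """Vectorized photon generation for a batch of transits.

    Thinning against the per-transit maximum brightness makes counts in
    each excitation phase exactly Poisson with rate brightness x time.
    Returns integer timestamps (us) and channel codes, unsorted.
    """
    dur_ms = dur_us / 1000.0
    r_dex = b_dex + direct_excitation
    rmax = np.maximum(r_dex, b_aex)
    n_cand = rng.poisson(rmax * dur_ms)
    total = int(n_cand.sum())
    if total == 0:
        return (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.uint8))
    tr = np.repeat(np.arange(starts_us.size), n_cand)
    ts = (starts_us[tr] + rng.random(total) * dur_us[tr]).astype(np.int64)
    full = 2 * period_us
    is_aex = (ts % full) >= period_us
    rate = np.where(is_aex, b_aex[tr], r_dex[tr])
    keep = rng.random(total) * rmax[tr] < rate
    ts, tr, is_aex = ts[keep], tr[keep], is_aex[keep]

    ch = np.empty(ts.size, dtype=np.uint8)
    ch[is_aex] = ACCEPTOR  # only the acceptor absorbs red excitation
    dex = ~is_aex
    ndex = int(dex.sum())
    if ndex:
        # route via FRET; surviving donor photons may leak into the
        # acceptor channel; direct excitation adds acceptor-channel photons
        p_direct = (direct_excitation
                    / np.maximum(r_dex[tr[dex]], 1e-300))
        u = rng.random(ndex)
        e_eff = fret_e[tr[dex]]
        p_acc = p_direct + (1 - p_direct) * (
            e_eff + (1 - e_eff) * donor_leakage)
        ch[np.flatnonzero(dex)] = np.where(u < p_acc, ACCEPTOR, DONOR)
    return ts, ch


def simulate_photon_stream(config: SimConfig):
    """Simulate a photon stream (without aggregates).

    Returns
    -------
    stream : PhotonStream
    truth : pandas.DataFrame
        Ground-truth transit intervals with columns ``burst_start_us,
        burst_end_us, species, is_aggregate``.
    """
    rng = _default_rng(config, 0)
    dur_total_us = config.duration_s * 1e6
    n_tr = rng.poisson(config.transit_rate_per_s * config.duration_s)
    starts = np.sort(rng.uniform(0, dur_total_us, n_tr))
    fracs = np.array([s.fraction for s in config.species])
    sp_idx = rng.choice(len(config.species), size=n_tr, p=fracs)
    d_rate = np.array([s.diffusion_rate_D for s in config.species])
    dur_ms = rng.exponential(1.0 / d_rate[sp_idx]) if n_tr else np.empty(0)
    dur_us = dur_ms * 1000.0

    b_dex = np.array([s.brightness_dex for s in config.species])[sp_idx]
    b_aex = np.array([s.brightness_aex for s in config.species])[sp_idx]
    fret = np.array([s.fret_e for s in config.species])[sp_idx]
    ts, ch = _emit_transit_photons(
        rng, starts, dur_us, b_dex, b_aex, fret,
        config.alternation_period_us, config.donor_leakage,
        config.direct_excitation)

    # uniform Poisson background per channel
    parts_ts, parts_ch = [ts], [ch]
    for rate, code in ((config.background_rate_donor, DONOR),
                       (config.background_rate_acceptor, ACCEPTOR)):
        n_bg = rng.poisson(rate * config.duration_s)
        bt = rng.uniform(0, dur_total_us, n_bg).astype(np.int64)
        parts_ts.append(bt)
        parts_ch.append(np.full(n_bg, code, dtype=np.uint8))
    all_ts = np.concatenate(parts_ts)
    all_ch = np.concatenate(parts_ch)
    order = np.argsort(all_ts, kind="stable")
    stream = PhotonStream(all_ts[order], all_ch[order],
                          config.alternation_period_us,
                          meta={"seed": config.seed})
    truth = pd.DataFrame({
        "burst_start_us": starts.astype(np.int64),
        "burst_end_us": (starts + dur_us).astype(np.int64),
        "species": [config.species[i].name for i in sp_idx],
        "is_aggregate": np.zeros(n_tr, dtype=bool),
    })
    return stream, truth


def inject_aggregates(stream: PhotonStream, config: SimConfig):
    """Insert runs of consecutive bright high-E transits into a stream.

    Aggregates diffuse slowly, so transit durations use the slowest
    species' rate; brightness is 2-5x the first species' and the apparent
    FRET of each run is drawn above ``aggregate_e_min``. Returns the
    (re-sorted) stream and a ground-truth table of the injected transits.
    """
    empty = pd.DataFrame(columns=["burst_start_us", "burst_end_us",
                                  "species", "is_aggregate"])
    if config.aggregate_burst_runs == 0:
        return stream, empty
    rng = _default_rng(config, 1)
    lo, hi = config.aggregate_run_length_range
    f_lo, f_hi = config.aggregate_brightness_factor
    d_agg = min(s.diffusion_rate_D for s in config.species)
    base = config.species[0]

    starts_list, durs_list, runs = [], [], []
    dur_total_us = config.duration_s * 1e6
    for _ in range(config.aggregate_burst_runs):
        k = int(rng.integers(lo, hi + 1))
        t0 = rng.uniform(0, dur_total_us)
        durs = rng.exponential(1.0 / d_agg, size=k) * 1000.0  # us
        gaps = rng.uniform(1500.0, 3000.0, size=k)
        t = t0
        for d, g in zip(durs, gaps):
            starts_list.append(t)
            durs_list.append(d)
            t += d + g
        runs.append(k)

    starts = np.array(starts_list)
    dur_us = np.array(durs_list)
    n = starts.size
    factor = rng.uniform(f_lo, f_hi, size=n)
    e_lo = min(config.aggregate_e_min + 0.02, 0.99)
    e_run = rng.uniform(e_lo, 0.995, size=config.aggregate_burst_runs)
    fret = np.repeat(e_run, runs)
    ts, ch = _emit_transit_photons(
        rng, starts, dur_us, base.brightness_dex * factor,
        base.brightness_aex * factor, fret, config.alternation_period_us,
        config.donor_leakage, config.direct_excitation)
    order = np.argsort(ts, kind="stable")
    agg_stream = PhotonStream(ts[order], ch[order],
                              config.alternation_period_us)
    merged_ts = np.concatenate([stream.timestamps_us, agg_stream.timestamps_us])
    merged_ch = np.concatenate([stream.channel, agg_stream.channel])
    order = np.argsort(merged_ts, kind="stable")
    out = PhotonStream(merged_ts[order], merged_ch[order],
                       config.alternation_period_us, dict(stream.meta))
    truth = pd.DataFrame({
        "burst_start_us": starts.astype(np.int64),
        "burst_end_us": (starts + dur_us).astype(np.int64),
        "species": "aggregate",
        "is_aggregate": np.ones(n, dtype=bool),
    }).sort_values("burst_start_us", ignore_index=True)
    return out, truth


def simulate_measurement(config: SimConfig):
    """Full simulated measurement: molecule transits plus aggregates.

    Returns the photon stream and the combined ground-truth table sorted
    by transit start.
    """
    stream, truth = simulate_photon_stream(config)
    stream, agg_truth = inject_aggregates(stream, config)
    truth = pd.concat([truth, agg_truth], ignore_index=True)
    truth = truth.sort_values("burst_start_us", ignore_index=True)
    return stream, truth


# ---------------------------------------------------------- burst shortcuts

def simulate_burst_table(config: SimConfig, n_bursts: int,
                         rng: np.random.Generator | None = None) -> BurstSet:
    """Draw a burst table directly, bypassing photon-level simulation.

    Per burst: species by fraction, duration exponential with the species'
    rate D, donor-excitation photon count Poisson with brightness x half
    the duration (the other half is red excitation), acceptor routing
    binomial with the species' apparent FRET.
    """
    if n_bursts <= 0:
        raise ValueError("n_bursts must be positive")
    if rng is None:
        rng = _default_rng(config, 2)
    fracs = np.array([s.fraction for s in config.species])
    sp = rng.choice(len(config.species), size=n_bursts, p=fracs)
    d_rate = np.array([s.diffusion_rate_D for s in config.species])[sp]
    dur_ms = rng.exponential(1.0 / d_rate)
    b_dex = np.array([s.brightness_dex for s in config.species])[sp]
    b_aex = np.array([s.brightness_aex for s in config.species])[sp]
    fret = np.array([s.fret_e for s in config.species])[sp]
    n_dex = rng.poisson(b_dex * dur_ms / 2.0)
    n_da = rng.binomial(n_dex, fret)
    n_dd = n_dex - n_da
    n_aa = rng.poisson(b_aex * dur_ms / 2.0)
    gaps_us = rng.exponential(1e6 / config.transit_rate_per_s, size=n_bursts)
    start_us = np.cumsum(gaps_us).astype(np.int64)
    end_us = start_us + (dur_ms * 1000).astype(np.int64)
    bs = BurstSet.from_counts(start_us, end_us, n_dd, n_da,
                              np.zeros(n_bursts, dtype=np.int64), n_aa,
                              simulated=True, seed=config.seed)
    bs.df["species"] = [config.species[i].name for i in sp]
    return bs


def simulate_titration(kd: float, concentrations, n_bursts_per_point: int,
                       seed: int = 0) -> pd.DataFrame:
    """Equilibrium titration: bound fraction c/(Kd + c) with binomial
    sampling noise at ``n_bursts_per_point`` molecules per concentration."""
    if kd <= 0:
        raise ValueError("kd must be positive")
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be >= 0")
    rng = np.random.default_rng(seed)
    p = conc / (kd + conc)
    k = rng.binomial(n_bursts_per_point, p)
    return pd.DataFrame({"concentration": conc,
                         "bound_fraction": k / n_bursts_per_point,
                         "n": n_bursts_per_point})


def simulate_dissociation_timecourse(koff: float, times, n_per_point: int,
                                     seed: int = 0) -> pd.DataFrame:
    """Dissociation time course: bound fraction exp(-koff * t) (koff per
    minute, t in minutes) with binomial sampling noise."""
    if koff < 0:
        raise ValueError("koff must be >= 0")
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    rng = np.random.default_rng(seed)
    p = np.exp(-koff * t)
    k = rng.binomial(n_per_point, p)
    return pd.DataFrame({"time_min": t, "bound_fraction": k / n_per_point,
                         "n": n_per_point})
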