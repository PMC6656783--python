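"""End-to-end pipeline: simulate -> burst search -> threshold -> species
selection -> aggregate filter -> mixture fit -> diffusion / bound fractions.

Driven by a single YAML (or dict) configuration with one section per stage;
all stage defaults are the standard analysis parameters (L = 25, M = 15,
T = 500 us, 250-photon threshold, n = 3, e = 0.9, Delta = 200 us,
t1 = 2 ms, t2 = 8 ms). A run writes its outputs plus a manifest recording
the seed, every stage's parameters and the SHA-256 of every output, so a
rerun of the same manifest reproduces byte-identical files.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .aggregate_filter import FilterParams, apply_filter
from .burst_search import (BurstSearchParams, burst_search, select_species,
                           threshold_bursts)
from .diffusion import (burst_duration_histogram, estimate_D,
                        per_state_bound_fraction)
from .io import read_stream_csv, read_stream_hdf5, write_stream_csv
from .mixture import select_model, state_populations
from .simulate import SimConfig, SimSpecies, simulate_measurement

log = logging.getLogger("alexburst.pipeline")

DEFAULT_SPECIES_WINDOW = (0.3, 0.8)


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "alexburst_run"
    simulation: dict = field(default_factory=dict)
    input_stream: str | None = None     # skip simulation when given
    write_stream: bool = False
    search: dict = field(default_factory=dict)
    species_selection: dict = field(default_factory=dict)
    filter: dict = field(default_factory=dict)
    mixture: dict = field(default_factory=dict)
    diffusion: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def sim_config(self) -> SimConfig:
        sim = dict(self.simulation)
        species = [SimSpecies(**sp) for sp in sim.pop("species", [])]
        if not species:
            raise ValueError("simulation.species must be provided")
        return SimConfig(species=species, seed=self.seed, **sim)


@dataclass
class RunManifest:
    version: str
    seed: int
    stages: dict
    outputs: dict            # name -> {path, sha256}

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name):
    log.info("stage: %s", name)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every configured stage in order and write a manifest.

    A stage failure raises with the stage name in the message.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: dict = {}
    outputs: dict = {}

    def record(name: str, path: Path):
        outputs[name] = {"path": str(path), "sha256": _sha256(path)}

    def fail(stage: str, exc: Exception):
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # ------------------------------------------------ acquire photon stream
    try:
        if config.input_stream is not None:
            _stage("load")
            p = Path(config.input_stream)
            if not p.exists():
                raise FileNotFoundError(p)
            stream = (read_stream_hdf5(p) if p.suffix in (".h5", ".hdf5")
                      else read_stream_csv(p))
            stages["load"] = {"input": str(p)}
        else:
            _stage("simulate")
            sim = config.sim_config()
            stream, truth = simulate_measurement(sim)
            truth_path = outdir / "ground_truth.csv"
            truth.to_csv(truth_path, index=False)
            record("ground_truth", truth_path)
            stages["simulate"] = {"seed": sim.seed,
                                  "n_photons": len(stream),
                                  "n_transits": int(len(truth))}
            if config.write_stream:
                sp = outdir / "stream.csv"
                write_stream_csv(stream, sp)
                record("stream", sp)
    except Exception as exc:  # noqa: BLE001 - stage name context
        fail("simulate/load", exc)

    # ------------------------------------------------------------- search
    try:
        _stage("search")
        params = BurstSearchParams(**config.search)
        bursts = burst_search(stream, params)
        bursts = threshold_bursts(bursts, params.min_total_photons)
        sel = config.species_selection
        s_lo, s_hi = (sel.get("s_min", DEFAULT_SPECIES_WINDOW[0]),
                      sel.get("s_max", DEFAULT_SPECIES_WINDOW[1]))
        bursts = select_species(bursts, s_lo, s_hi)
        path = outdir / "bursts.csv"
        bursts.to_csv(path)
        record("bursts", path)
        stages["search"] = {"params": asdict(params),
                            "s_window": [s_lo, s_hi],
                            "n_bursts": len(bursts)}
    except Exception as exc:
        fail("search", exc)

    # ------------------------------------------------------------- filter
    try:
        _stage("filter")
        fparams = FilterParams(**config.filter)
        bursts, report = apply_filter(bursts, fparams)
        path = outdir / "bursts.filtered.csv"
        bursts.to_csv(path)
        record("bursts_filtered", path)
        rpath = outdir / "filter.json"
        rpath.write_text(json.dumps(report.to_dict(), indent=2,
                                    sort_keys=True))
        record("filter_report", rpath)
        stages["filter"] = report.to_dict()
    except Exception as exc:
        fail("filter", exc)

    # ------------------------------------------------------------ mixture
    try:
        _stage("mixture")
        mx = dict(config.mixture)
        sigma_bounds = (mx.pop("sigma_lo", 0.015), mx.pop("sigma_hi", 0.10))
        result = select_model(bursts.df["E_star"].dropna().to_numpy(),
                              sigma_bounds=sigma_bounds, **mx)
        pops = state_populations(result)
        states = {"fit": result.to_dict(), "populations_pct": pops}
        path = outdir / "states.json"
        path.write_text(json.dumps(states, indent=2, sort_keys=True))
        record("states", path)
        stages["mixture"] = states
    except Exception as exc:
        fail("mixture", exc)

    # ---------------------------------------------------------- diffusion
    try:
        _stage("diffusion")
        dcfg = dict(config.diffusion)
        delta = dcfg.get("delta_us", 200.0)
        t1, t2 = dcfg.get("t1_ms", 2.0), dcfg.get("t2_ms", 8.0)
        hist = burst_duration_histogram(bursts, delta)
        est = estimate_D(hist, t1, t2)
        diff = {"overall": est.to_dict()}
        if "d1" in dcfg and "d2" in dcfg and "state_windows" in dcfg:
            windows = {k: tuple(v)
                       for k, v in dcfg["state_windows"].items()}
            per_state = per_state_bound_fraction(
                bursts, windows, dcfg["d1"], dcfg["d2"], delta, t1, t2,
                min_bursts=dcfg.get("min_bursts", 1000))
            diff["per_state"] = {
                name: {"n_bursts": r.n_bursts, "flagged": r.flagged,
                       "estimate": (r.estimate.to_dict()
                                    if r.estimate else None)}
                for name, r in per_state.items()}
        path = outdir / "diffusion.json"
        path.write_text(json.dumps(diff, indent=2, sort_keys=True))
        record("diffusion", path)
        stages["diffusion"] = diff
    except Exception as exc:
        fail("diffusion", exc)

    manifest = RunManifest(__version__, config.seed, stages, outputs)
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest
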