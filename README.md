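# alexburst

Burst analysis for microsecond alternating-laser-excitation (μs-ALEX)
single-molecule FRET measurements of freely diffusing molecules, built for
studies of conformational equilibria and ribosome association of the
twin-ATPase ribosome-recycling factor ABCE1 — and for any experiment with
the same structure: a labeled protein whose conformational states appear as
FRET sub-populations, and whose binding to a much larger partner appears as
slower diffusion.

## What it computes

In a confocal μs-ALEX experiment, single labeled molecules diffuse through
the excitation volume in milliseconds while green and red lasers alternate
every 50 μs. Each transit produces a photon burst from which two
ratiometric observables are computed:

* apparent FRET efficiency
  **E\* = n(Dex→Aem) / [n(Dex→Dem) + n(Dex→Aem)]** — sensitized acceptor
  emission over all emission during donor excitation (uncorrected);
* stoichiometry
  **S = n(Dex) / [n(Dex) + n(Aex→Aem)]** — separating donor-only (S≈1),
  acceptor-only (S≈0) and doubly labeled molecules (intermediate S).

The package implements the complete analysis chain:

1. **Burst search** — sliding-window detection (≥ M photons within T μs,
   runs of ≥ L photons; defaults M = 15, T = 500 μs, L = 25), in
   all-photon or dual-color mode (the criterion must hold in both
   excitation streams), plus a > 250-photon intensity threshold.
2. **Aggregate filter** — a per-burst hypothesis test on the temporal
   correlation of high-E bursts (Bernoulli indicators Xᵢ = [Eᵢ > e],
   binomial neighbor statistic Tᵢ over n neighbors per side, critical
   region p̂′ + w·√(p̂′(1−p̂′))) that removes the runs of spurious
   high-FRET bursts produced by fluorescent aggregates while removing only
   a few percent of independent bursts.
3. **Gaussian-mixture state decomposition** — weighted least-squares fit
   of 1–3 Gaussian components to the E\* histogram with constrained widths;
   the minimal adequate model gives the populations of the open,
   intermediate and closed conformational states.
4. **Diffusion from burst durations** — the tail of the burst-duration
   histogram follows P(t; D) = N·D·e^(−Dt), so the OLS slope of log(mᵢ)
   over a tail window (2–8 ms) estimates a relative diffusion constant D
   (ms⁻¹). For a bound/free mixture,
   P(t; D₁, D₂, A) = N·[A·D₁e^(−D₁t) + (1−A)·D₂e^(−D₂t)],
   and the bound fraction A is recovered by matching the same slope
   functional (the constant N cancels under the log). A Stokes–Einstein
   check (D ∝ m^(−1/3)) relates diffusion ratios to molecular masses.
5. **Binding kinetics** — hyperbolic titration fits (K_D), exponential
   dissociation time courses (k_off), and the chain
   k_on = k_off / K_D, τ_assoc = 1/(k_on·c).
6. **Anisotropy calibration** — r = (I_VV − G·I_VH)/(I_VV + 2G·I_VH) with
   G = I_HV/I_HH.

A photon-level simulator with the same statistical assumptions (Poisson
transits, exponential durations, Poisson emission, binomial FRET routing,
Poisson background, injectable aggregate runs) makes every stage testable
without measurement data; ground-truth transit tables are returned for
validation.

## Worked example

```python
from alexburst import (SimConfig, SimSpecies, simulate_measurement,
                       burst_search, threshold_bursts, select_species,
                       apply_filter, select_model, state_populations,
                       burst_duration_histogram, estimate_D, kinetics_chain)

species = [  # a free protein sampling three conformational states
    SimSpecies("open",         fret_e=0.30, diffusion_rate_D=1.10, fraction=0.50),
    SimSpecies("intermediate", fret_e=0.60, diffusion_rate_D=1.10, fraction=0.30),
    SimSpecies("closed",       fret_e=0.90, diffusion_rate_D=1.10, fraction=0.20),
]
cfg = SimConfig(species=species, duration_s=4800.0, transit_rate_per_s=5.0, seed=7)
stream, truth = simulate_measurement(cfg)
print(f"simulated {len(stream):,} photons, {len(truth):,} molecule transits")

bursts = select_species(threshold_bursts(burst_search(stream), 250), 0.3, 0.8)
bursts, report = apply_filter(bursts)
print(f"{len(bursts):,} donor-acceptor bursts after thresholding and filtering "
      f"(removed {100*report.removed_fraction:.1f}%)")

fit = select_model(bursts.df["E_star"].dropna().to_numpy())
for state, pct in state_populations(fit).items():
    print(f"  {state:12s} {pct:5.1f}%")

est = estimate_D(burst_duration_histogram(bursts, 200.0))
print(f"relative diffusion constant D = {est.D_hat:.2f} /ms "
      f"(95% CI {est.ci95[0]:.2f}-{est.ci95[1]:.2f})")

chain = kinetics_chain(kd_M=20e-9, koff_per_min=0.5, conc_M=1e-6)
print(f"kon = {chain.kon:.2e} /M/s, mean association time at 1 uM = "
      f"{chain.tau_assoc:.1f} s")
```

Output:

```
simulated 15,353,902 photons, 24,146 molecule transits
10,912 donor-acceptor bursts after thresholding and filtering (removed 0.1%)
  open          50.4%
  intermediate  29.9%
  closed        19.7%
relative diffusion constant D = 1.12 /ms (95% CI 1.02-1.22)
kon = 4.17e+05 /M/s, mean association time at 1 uM = 2.4 s
```

The mixture decomposition recovers the generating state populations
(50/30/20%) to within a fraction of a percentage point; the diffusion
estimate recovers the generating rate (1.10 ms⁻¹) within its confidence
interval; and the kinetic chain turns a dissociation rate of 0.5 min⁻¹ and
K_D = 20 nM into an association rate of ≈ 4·10⁵ M⁻¹s⁻¹, i.e. binding
within ~2.5 s at 1 μM partner concentration.

The same stages are available from the shell:

```sh
alexburst simulate  --config sim.yaml --out stream.h5 --seed 7
alexburst search    --in stream.h5 --out bursts.csv
alexburst filter    --in bursts.csv --out bursts.filtered.csv --report filter.json
alexburst fitfret   --in bursts.filtered.csv --out states.json
alexburst diffusion --in bursts.filtered.csv --d1 0.60 --d2 1.10 --out diffusion.json
alexburst kinetics  kon --koff 0.5 --kd-nM 20 --conc-uM 1
alexburst pipeline  --config run.yaml   # all of the above from one YAML
```

## Layout

```
src/alexburst/
  photons.py            photon-stream container (timestamps, channels, ALEX phase)
  simulate.py           photon-level and burst-level synthetic data
  burst_search.py       sliding-window burst detection, E*/S, ES histograms
  aggregate_filter.py   burst-correlation aggregate filter
  mixture.py            Gaussian-mixture state decomposition
  diffusion.py          burst-duration diffusion and bound-fraction estimators
  kinetics.py           titration/time-course fits, kinetic arithmetic
  anisotropy.py         steady-state anisotropy calibration
  pipeline.py, cli.py   YAML-driven orchestration and command-line interface
docs/methods.md         model assumptions, defaults, numerical choices
tests/                  unit, property and acceptance suites
```
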