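# Methods

This note records the models implemented by `alexburst`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
data generator does and does not emulate.

## Measurement model

A μs-ALEX experiment records photons from single molecules diffusing
through a confocal volume while two lasers alternate every 50 μs. The
package represents a measurement as a time-ordered array of
integer-microsecond timestamps with a detection channel (donor/acceptor
emission); the excitation label is not stored but derived, `t mod 2P < P`
giving the donor-excitation phase for period `P`. Quantizing to 1 μs
matches event-timer resolution scales and makes simulated files bit-exact
under a fixed seed.

## Burst search

A photon is qualified when at least `M` photons of the tested stream fall
within a centered window `[t − T/2, t + T/2]`; maximal runs of qualified
photons with at least `L` photons are bursts. Defaults `M = 15`,
`T = 500 μs`, `L = 25`, with an additional strict `> 250` total-photon
threshold — the standard settings for this type of analysis. Window
centering is a convention (the criterion is symmetric and the oracle tests
pin it down). Two design points deserve note:

* **Dual-color mode** requires the M/T criterion to hold simultaneously in
  the donor-excitation stream and the acceptor-excitation stream at every
  photon. This is the dual-channel convention that selects doubly labeled
  molecules. An alternative reading — intersecting the qualified *time
  intervals* of the two streams — degenerates on short time scales because
  Dex and Aex photons never coexist within one alternation half-period;
  the per-photon conjunction has no such pathology and makes every
  dual-color burst a subset of an all-photon burst.
* Bursts separated by even one unqualified photon are distinct; there is
  no merge-gap parameter.

Per burst, counts are tallied by (excitation, channel). `E*` and `S` are
the uncorrected ratios; bursts with a zero denominator carry NaN for the
affected observable. `n_AexDem` (donor emission under red excitation) is
recorded but used by neither observable. No background subtraction, gamma
correction or distance conversion is applied anywhere — the analysis works
in uncorrected E\* throughout.

## Aggregate filter

Fluorescent aggregates generate runs of roughly 6–12 consecutive bursts
with spuriously high E. The filter tests, for each high-E burst, whether
its temporal neighborhood contains more high-E bursts than expected under
independence: with `X_i = [E_i > e]`, `T_i` the number of high-E bursts
among `n` neighbors on each side, and `p̂′` the dataset high-E fraction,
burst `i` is removed iff `X_i = 1` and `T_i/2n > p̂′ + w·√(p̂′(1−p̂′))`.
Defaults `n = 3`, `e = 0.9`; `w` defaults to 1.0, the midpoint of the
useful 0.5–2 range (smaller `w` removes more).

Conventions where the test statistic leaves freedom: `E* = e` exactly (a
measure-zero event) and NaN E\* count as `X_i = 0`; neighbors beyond the
dataset edges count as 0 (conservative — less removal at the edges); `p̂′`
is estimated once from the full input, not re-estimated iteratively; the
acceptance region is closed at its bound (removal requires strictly
exceeding it). `null_removal_fraction` gives the exact closed-form
expectation `p′·P[Binom(2n, p′) > 2n(p′ + w√(p′(1−p′)))]` for independent
bursts; at `p′ = 0.3`, `w = 0.5` it is 2.11%, and Monte-Carlo runs agree
within binomial error. The filter is designed for aggregate loads up to
~15% of bursts; if aggregates dominate the dataset, `p̂′` itself is
inflated and sensitivity degrades — that regime is outside the test's
design.

## Mixture decomposition of E\*

E\* histograms (bin width 0.02) of the doubly labeled population (selected
by intermediate S, default window 0.3–0.8) are fitted with sums of 1–3
Gaussians by least squares, weighted by √count (Poisson). Means are free
in [0, 1]; widths are constrained to a configurable interval, default
**[0.015, 0.10]**: the width of a static state is set by shot noise,
σ ≈ √(E(1−E)/N), which for bursts of a few hundred donor-excitation
photons ranges from ~0.04 at E ≈ 0.5 down to ~0.02 at E ≈ 0.9. A higher
floor (e.g. 0.03) pins the high-E component against its bound and
measurably misallocates its weight; in practice the bounds would be
calibrated with static double-labeled DNA standards. State weights are
component *areas* (amplitude × σ), normalized — amplitudes alone are
bin-width dependent.

Initialization is a fixed, deterministic multi-start (top-k histogram
peaks, sample quantiles, equispaced positions); no random restarts, so a
fit is a pure function of the data.

Model order follows the minimum-number-that-fits rule, operationalized in
two steps: a model whose reduced χ² is already ≤ 1.5 is never extended
(additional components would fit counting noise — a pure
relative-improvement rule demonstrably overfits unimodal data); otherwise
one more component is accepted while it improves reduced χ² by more than
10% (relative) and introduces no component below 1% weight. States are
labelled open / intermediate / closed by ascending mean when three
components are present; populations are reported as percentages summing
to 100.

Resolution limits: a component below a few percent weight, or two
components closer than ~2σ, are not reliably separated at realistic burst
counts; the selection rule then prefers the smaller model.

## Burst-duration diffusion analysis

"Burst size" is read as burst **duration**: the bin size Δ is specified in
μs and the fit range in ms with D in ms⁻¹, units that only cohere for
durations. The histogram uses bins centered at `t = iΔ` (default
Δ = 200 μs, configurable 200–400 μs with more data warranting wider bins).
The tail is modelled as `P(t; D) = N·D·e^(−Dt)`; `D` is relative (it
absorbs the excitation-volume geometry) and `N` is never estimated.

`estimate_D` is the negative OLS slope of `log mᵢ` vs `tᵢ` over bins with
`t₁ ≤ t ≤ t₂` (defaults 2 and 8 ms); zero-count bins are dropped (log
undefined; no pseudo-counts). The estimator is exact on noiseless
exponential histograms. Its 95% CI uses a Student-t quantile with the
**HC3 heteroscedasticity-robust** slope standard error: the variance of a
log-count grows along the tail as counts shrink, and the homoscedastic
textbook SE undercovers by several percent in exactly the regime the
estimator is used in (verified by seeded coverage studies: ≥ 92/100 at
20,000 durations across D = 0.60–1.10 ms⁻¹). The point estimate remains
the plain OLS slope.

Known bias: with few thousand bursts the far-tail bins hold 0–2 counts
each; dropping zeros while keeping ones flattens the apparent slope and
biases D̂ low by up to ~10% at ~2,000 bursts. The bias vanishes with
event count — analyses aiming at percent-level D should use ≥ 20,000
bursts, which is why per-state binding analyses require long measurements
(> 25,000 events).

For a bound/free mixture the tail is
`P(t; D₁, D₂, A) = N·[A·D₁e^(−D₁t) + (1−A)·D₂e^(−D₂t)]`. The bound
fraction is estimated by slope matching: apply the same OLS slope
functional to `log P(tᵢ; D₁, D₂, A)` over the same bins used for the
measured slope, and solve for A by bracketed bisection on [0, 1]
(tolerance far below 10⁻³; verified against a 10⁻³-step grid search). The
model slope is strictly monotone in A between −D₂ and −D₁, so the root is
unique; a measured slope outside that range clamps Â to the nearer
endpoint with a diagnostic flag. Near A = 1 the slope depends only weakly
on A, so sampling noise in the measured slope widens the inverse map
there. Per-state bound fractions partition bursts by disjoint E\* windows
(default floor 1,000 bursts per window; smaller subsets are flagged, not
estimated).

The Stokes–Einstein check returns `(m₂/m₁)^(1/3)` as the predicted ratio
of diffusion constants of a small free species (mass m₁) to a large
complex (mass m₂), e.g. 3.3 for 70 kDa vs 2.5 MDa — an order-of-magnitude
consistency check, not a calibration (shape, hydration and volume effects
are ignored).

## Binding kinetics

Titrations are fitted with `f(c) = c/(K_D + c)`, valid when the labeled
species is in trace amounts so free ≈ total ligand; a quadratic depletion
model is available via `total_labeled`. Time courses are fitted with
`f(t) = f₀·e^(−k_off·t)`. Fits are unweighted unless per-point molecule
counts are supplied, in which case binomial weights are used. `k_off` is
stored per minute (the natural reporting unit for minute-scale
dissociation) and converted to s⁻¹ only inside
`k_on = k_off/K_D`; the mean association time is `1/(k_on·c)`. With
k_off = 0.5 min⁻¹ and K_D = 20 nM this chain gives
k_on = 4.2·10⁵ M⁻¹s⁻¹ and ~2.4 s to bind at 1 μM partner.

## Synthetic data generator

The generator emulates exactly the statistics the estimators assume:

* transit starts are Poisson in time (default 5 s⁻¹ — single-molecule
  occupancy of well under 1% for millisecond transits, as in the 10–100 pM
  concentration regime these measurements use);
* transit durations are exponential with the species' rate D;
* emission is Poisson with a rectangular intensity profile (brightness
  defaults 400/300 photons·ms⁻¹ under green/red excitation), implemented
  by thinning so per-phase counts are exactly Poisson;
* donor-excitation photons route to the acceptor channel with probability
  E\* (binomial FRET); donor leakage and direct acceptor excitation
  default to 0 (uncorrected-E\* analysis) but are exposed as scalars;
* background is uniform Poisson per channel (defaults 1000/600 s⁻¹);
* aggregates are runs of 6–12 consecutive transits at 2–5× brightness
  with E drawn above 0.9, diffusing at the slowest species' rate,
  1.5–3 ms apart.

Everything derives from a single integer seed (independent substreams per
purpose), so identical configs reproduce identical photon tables
bit-for-bit.

What is *not* emulated — and hence what passing tests do not demonstrate
about real data: no Gaussian focal profile or 3-D Brownian paths (the
estimators never use intra-burst intensity shape; the exponential-duration
assumption is imposed, not derived), no triplet blinking or
photobleaching, no detector afterpulsing or dead time, no spectral
crosstalk beyond the two optional scalars. Real burst-duration tails also
deviate from single exponentials at short times; the 2–8 ms fit window is
what makes the model usable there.

One consequence of photon-level realism worth knowing: the > 250-photon
threshold preferentially keeps slow (long-transit) molecules, so when
states differ in their bound (slow) fraction, the composition of the
*detected* burst set differs from molar fractions by this selection
effect. The mixture fit faithfully recovers the detected-ensemble
composition, and tail-based bound-fraction estimates are unaffected
(thresholding only removes sub-millisecond bursts, outside the fit
window). End-to-end tests therefore compare mixture weights against the
ground-truth composition of the analyzed burst set and Â against the
generating bound fractions.

Transit overlap is the other occupancy-driven artifact: at high transit
rates two molecules can co-occupy the volume and merge into one long
burst, fattening the duration tail and biasing D̂ low (visible at 15 s⁻¹
and above). The default 5 s⁻¹ keeps merging below ~1% of bursts.

## Problem sizes

Seeded test and acceptance runs use: 20,000 durations × 100 replicates for
CI coverage; 50,000 independent bursts for the filter's null behavior; 200
random streams of ≤ 2,000 photons for brute-force equivalence; 5,000
bursts for mixture recovery; and a 12,000 s photon-level simulation at
5 transits·s⁻¹ (~48 M photons, ~33,000 analyzed bursts) for the end-to-end
recovery of state populations and per-state bound fractions — comfortably
above the > 25,000-event level that per-state binding estimates need.

## Anisotropy

`r = (I_VV − G·I_VH)/(I_VV + 2G·I_VH)` with `G = I_HV/I_HH` under
horizontal excitation. Intensities must be background-corrected by the
caller. Scale-invariance and monotonicity in I_VH are asserted as
properties; no distance or κ² analysis is performed.
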