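# Methods

## The measurement model

A protein of interest carries a self-labeling tag that binds chloroalkane
dye ligands covalently and irreversibly. Two spectrally distinct ligands are
administered sequentially: the *pulse* marks the protein present at time
zero, the *chase* marks protein synthesized during the interval `dt` (days).
Under steady-state turnover with synthesis rate `r` (amount/day) and
first-order degradation rate `a` (1/day), the pool is `P = r/a` and the
surviving pulse fraction after `dt` is

    fraction pulse = pulse / (pulse + chase) = exp(-dt / tau),
    tau = 1 / a = dt / ln(1 / fraction pulse).

All logarithms in the package are natural; `tau` is the *mean lifetime*
(half-life / ln 2). Total tagged protein is pulse + chase, so the method also
reports protein-level changes.

## Labeling kinetics (`pulsechase.kinetics`)

The simulator integrates mass-action kinetics of seven species: unlabeled
protein, pulse-bound protein, chase-bound protein, and free pulse/chase dye
in a cytosol compartment (volume fixed at 1) and a lipid compartment.
Degradation acts identically on unlabeled and dye-bound protein. Injections
are instantaneous additions to the cytosol free-dye pool. Cumulative
eliminated and degraded-bound dye are carried as explicit states so the dye
mass balance (dose = free + bound + cleared + degraded) can be audited at
every output time; it holds to ~1e-11 at the default tolerances.

*Binding.* In vivo, tag-ligand binding is orders of magnitude faster than
turnover. It is modeled as mass action with a surrogate rate chosen so the
pseudo-first-order binding half-time against the steady-state pool is 1e-3
of the effective clearance constant. A convergence test doubles (and
10x-es) the rate and verifies the readout fraction moves by less than 1e-3
in absolute fraction. Setting the clearance rate to `inf` selects a
closed-form ideal limit (instantaneous binding, then instantaneous clearance
of surplus dye) used for exactness tests.

*Clearance.* Free dye exchanges between cytosol and lipid and is eliminated
from cytosol. Measured in vivo decays are multi-exponential with an
effective (1/e) constant of roughly 82 minutes; the underlying compartment
parameters are not published. `ClearanceParams.with_effective_minutes(82)`
therefore rescales a canonical shape so the cytosol bolus response crosses
1/e at exactly 82 min. The default shape is fast-dominant (about 60% of the
decay at ~1 h, 40% at ~2.4 h). This choice matters: a heavy lipid reservoir
with the same 1/e crossing extends the residual-labeling window into days
and inflates the lifetime bias at dye excess severalfold, contradicting the
observed behavior of the method; the fast-dominant shape reproduces the
"small error under dye excess" regime (~1.1% at dose 2x pool, tau = 14 d).

*Readout convention.* `standard_schedule(dt)` places the readout five
effective clearance constants after the chase injection, so the chase ligand
has the same residual-labeling window as the pulse and chase labeling is
complete at readout.

## Estimation (`pulsechase.estimation`)

`lifetime_from_fraction` inverts the exponential survival; fractions at or
above 1 raise a distinct infinite-lifetime signal (or, opt-in, are clipped to
1 - 1e-12 with a warning for noisy per-pixel data). `multi_interval_fit`
pools (fraction, interval) observations — e.g. the three survival ratios of a
one-pulse/two-chase design, each paired with its own window — and fits a
single exponential by least squares; uncertainty is a seeded percentile
bootstrap over observations (default 1,000 resamples). The resampling unit
is the measurement; coverage of the 95% interval is ~94% in simulation for
designs with 8 or more animals and drops to ~89% at 5 animals, the usual
small-sample behavior of percentile intervals (a limitation to bear in mind
for very small cohorts — we verified that BCa, basic, stratified and
animal-level resampling do not repair it at that size).

`error_surface` maps the signed percent lifetime error over a grid of
dye:protein ratio and true lifetime. By default each cell uses the
matched-interval design `dt = tau_true` (the interval an experimenter would
choose), with readout per the standard schedule. Under this design
undersaturation (ratio < 1) biases lifetimes strongly low — in deep
undersaturation the error saturates near -24% independent of dose because
both dyes capture dose-limited samples of their target pools — while dye
excess biases mildly high (residual pulse ligand marks protein synthesized
during the clearance window), and accuracy improves with lifetime. At
exactly ratio 1 the error is slightly negative (clearance steals some dye
during labeling), so the sign dichotomy is asserted away from the saturation
boundary (ratios <= 0.5 vs >= 2). For lifetimes below roughly 100x the
clearance constant the pulse- and chase-side residual effects interleave and
the error is no longer monotone in lifetime; the default acceptance grid
spans 7-224 days, the regime the method targets.

## Non-steady-state correction (`pulsechase.nonsteady`)

If synthesis steps from `r` to `r*` at t = 0 while degradation is unchanged,
the pool relaxes as `P(t) = Pinf + (P0 - Pinf) exp(-a t)` and the mean age
of the pool is `1/a + t exp(-a t) (P0 - Pinf) / P(t)`, derived from the
accumulated ages of the original and newly synthesized populations. The bias
of a lifetime estimate taken during the transient is reported as the percent
deviation of the mean age from `1/a`; for a 20% synthesis increase measured
one lifetime after onset it is about -6.5% (extra young protein transiently
lowers the apparent lifetime). Arbitrary tabulated ramps `r*(t)` are handled
by an age-structured cohort integrator (trapezoidal, with automatic grid
doubling until successive estimates agree to 1e-4 relative), which doubles
as the independent oracle for the closed form (agreement to < 0.5% across
a \in {1/7, 1/14, 1/28}/day, r*/r \in {0.5, 1, 1.2, 2}, t up to 4 lifetimes).
An opt-in inversion solves the mean-age relation for the steady-state
lifetime given an observed age.

## Clearance and infusion fitting (`pulsechase.clearance`)

Bolus traces are fitted with `F(t) = a exp(-t/tau1) + b exp(-t/tau2) + c` by
bounded nonlinear least squares (amplitudes >= 0, time constants in
[0.1, 1e4] min), with 16 seeded restarts and fitting started at the
maximum-intensity sample so a captured injection rise is ignored. Reported
fits are canonically ordered `tau1 <= tau2`; a slow amplitude below 0.1% of
the total flags the second component unidentifiable. The *effective time
constant* summarizes the bi-exponential as the 1/e crossing of the
baseline-subtracted model (root of `a e^{-t/tau1} + b e^{-t/tau2} =
(a+b)/e`), which always lies between the two component constants; an
amplitude-weighted mean is available behind a flag. Infusion traces are
summarized by ordinary least-squares slope and intercept per pump window.

## Dye diffusion (`pulsechase.diffusion`)

A 1-D explicit finite-difference model: grid position 0 is a vessel into
which a fixed total dose is injected at a chosen rate (a.u. per step) and
which clears 1 a.u. per step; dye diffuses into the tissue with a
conservative flux update (reflecting boundaries, stability `D dt <= 1/2`).
Each step applies injection, then clearance, then diffusion, so a source at
or below the sink leaves no dye in tissue. Mass (injected - cleared -
in-tissue) balances to machine precision every step. The saturated width is
the contiguous run of positions from the vessel whose final concentration
reaches 90% of the configured saturation value. Defaults (512 positions,
D dt = 0.25, total dose 500, 250 steps) read the width out just as the dose
has been fully delivered at the slowest compared rate; later the vessel
re-absorbs near-vessel dye and the contiguous width collapses for all
rates. Across rates 2-10 a.u./step at fixed total dose the width is
non-decreasing in rate — faster injection outruns vessel clearance.

## Image quantification (`pulsechase.imagequant`)

Percentile normalization (0.3/99.7 anchors) feeds segmentation only;
quantification always uses raw intensities. Segmentation is a classical
stand-in (Gaussian smoothing, Otsu or absolute threshold, connected
components, size filter) for externally trained classifiers, whose label
maps are accepted anywhere a label map is expected. Per object, the local
background is the median of an annulus (inner margin 1 px, width 5 px,
both configurable) excluding all object pixels and an optional artifact
mask, with a flagged fall-back to the image-global robust background.
Intensities convert to micromolar as `max(I - background, 0) / slope`; the
annulus background already contains the calibration intercept. Fraction
pulse and lifetime follow per object or per pixel; per-pixel mode applies a
total-protein floor before the lifetime conversion so noise-dominated
ratios never produce lifetimes, and a 3x3 median filter precedes the
per-condition cap (uniform seeded subsample to <= 1,000 rows per
animal x region) used for downstream mixed-model tables. Region aggregation
drops configured atlas ids (root/fiber/ventricle stand-ins) and reports
them as excluded rows; the negative-control filter excludes regions whose
pulse *or* chase intensity fails mean + 2 SD of tag-free control animals
(>= 2 controls required per region).

With zero noise, exact calibration and perfect masks the pipeline
reproduces ground-truth lifetimes to float round-off — quantification is a
sequence of exact linear operations in that limit.

## Synthetic data (`pulsechase.synthetic`)

Generators are pure functions of (parameters, seed). Images place
non-overlapping uniform disks (nuclei, radius 10 px, with a matching
nuclear-stain channel) or Gaussian puncta (sigma 2 px); per object the
fraction pulse is exactly `exp(-dt/tau)` and pulse/chase micromolar amounts
split a 5 uM total. The forward model is linear calibration (default slope
40 intensity/uM, intercept 100) plus a smooth neuropil background
(optionally with a vertical gradient) and Poisson shot noise (80% of the
noise budget) with additive Gaussian read noise — the standard fluorescence
camera model; SNR is the mean object pulse amplitude over the total noise
SD. What the generator does *not* emulate: optical blur, bleaching, tile
stitching, anisotropic backgrounds, segmentation ambiguity of touching
cells; passing tests therefore validate the quantification arithmetic and
robustness to pixel noise, not performance on real histology. Region
datasets draw `lifetime = region mean + group effect + animal offset +
noise` with defaults mirroring a synaptic-protein experiment (region means
11-17 d, a -2.4 d enrichment effect on a 14.2 d baseline, animal SD 0.5 d,
residual SD 1.4 d, <= 1,000 pixels per condition). Clearance traces sample
a bi-exponential (defaults a=100, tau1=20 min, b=30, tau2=400 min, offset
5) on an uneven grid: 2-10 min spacing over the first 4 h, then 4-12 h
intervals to ~24 h, matching awake-imaging sessions; the denser early grid
is what makes the slow constant identifiable at noise SD 2.

## Rank statistics (`pulsechase.stats`)

For group sizes typical of whole-animal experiments the two-sided Wilcoxon
rank-sum test is computed exactly: W is the midrank sum of the first group
and the p value enumerates all C(n1+n2, n1) assignments of the pooled
(mid)ranks, conditional on observed ties. Complete separation at 4 vs 4
gives W = 26, p = 2/70 ~ 0.0286. Above a combined n of 12 a tie-corrected
normal approximation with continuity correction is used and flagged.
Percent changes between groups are `100 (v1 - v2) / v_ref` per matched
region; distribution summaries report the median and the fraction of
regions beyond a threshold (signed by default, absolute optional). Fitting
of mixed-effects models is deliberately out of scope — the package
guarantees only the capped long-table contract they consume.

## Numerical choices

- Stiff integrator: BDF, rtol 1e-8, atol 1e-10, each injection segment
  integrated in segment-local time (the system is autonomous) to avoid
  step-size underflow at late times; states clipped at 0 after a negativity
  audit against solver tolerance.
- Double-exponential restarts draw log-uniform time constants spanning
  1e-3 to 10x the trace span; the first start is deterministic.
- The exact rank-sum enumeration compares |W - E[W]| with a 1e-12 slack so
  midrank ties at the observed deviation count as at-least-as-extreme.
- Degenerate inputs raise typed errors (`DomainError`,
  `UndefinedFractionError`, `InfiniteLifetimeError`, `StabilityError`,
  `FitError`, `ResolutionError`) rather than returning sentinels.

## Problem sizes

Simulation studies use sizes a workstation handles in seconds while keeping
the statistics meaningful: 100-object images at 512x512 for recovery, 200
replicates for bootstrap coverage, 50 seeds for noisy clearance fits, 36
cells for the error surface. These are the package's test conditions, not
limits of the implementation.
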