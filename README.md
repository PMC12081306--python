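# pulsechase

Pulse-chase measurement of protein lifetime with self-labeling tags and
sequential dye ligands: the kinetic, statistical and image-analysis
machinery, testable end to end on synthetic data.

## The problem

Protein turnover in tissue can be measured by fusing a protein of interest
to a self-labeling tag (e.g. a HaloTag knock-in) and injecting two
spectrally distinct dye ligands in sequence. The first (*pulse*) covalently
marks all protein present at time zero; the second (*chase*) marks protein
synthesized during the interval Δt. Under steady-state exponential turnover
the surviving pulse fraction is

    fraction pulse = pulse / (pulse + chase) = e^(−Δt/τ)

so the mean lifetime is **τ = Δt / ln(1 / fraction pulse)** (τ = half-life
/ ln 2 = 1/degradation rate). Imaging both dyes yields lifetime maps from
whole-brain scale down to single synapses.

The package is for experimentalists and analysts running such experiments:
it simulates the labeling kinetics (including realistic dye clearance, to
choose doses and intervals), converts fraction-pulse measurements into
lifetimes with bootstrap confidence intervals, corrects for non-steady
synthesis, fits clearance/infusion traces, models dye diffusion from a
vessel, quantifies multichannel image stacks into per-object and per-region
lifetime tables, and provides the exact small-sample rank statistics used
for group comparisons. A synthetic-data module generates images, traces and
region tables with known ground truth so every step is verifiable.

## Worked example

```python
import numpy as np
from pulsechase import kinetics, estimation, imagequant, synthetic

# fraction pulse of 0.41 measured 14 days after the pulse
tau = estimation.lifetime_from_fraction(0.41, 14.0)
print(f"tau = {tau:.2f} days")

# simulate the same experiment with realistic dye clearance
cl = kinetics.ClearanceParams.with_effective_minutes(82.0)
system = kinetics.KineticSystem(synthesis_rate=1.0, degradation_rate=1/14,
                                dye_dose_pulse=28.0, dye_dose_chase=28.0,
                                clearance=cl)
schedule = kinetics.standard_schedule(14.0, cl)
traj = kinetics.simulate_pulse_chase(system, schedule)
fp = kinetics.fraction_pulse_at(traj, schedule.t_readout)
print(f"simulated fraction pulse = {fp:.4f}")
print(f"estimated tau = {estimation.lifetime_from_fraction(fp, 14.0):.2f} days"
      f" (true: 14.00)")

# recover lifetimes from a synthetic image
image, truth = synthetic.make_image(n_objects=100, tau_days=10.0,
                                    delta_t=7.0, snr=20.0, seed=0)
labels = imagequant.segment_objects(imagequant.normalize_channels(image))
table = imagequant.quantify(image, labels, truth.calibration, truth.delta_t)
print(f"{len(table)} nuclei, median lifetime = "
      f"{table['lifetime_days'].median():.2f} days (true: 10.00)")
```

prints

```
tau = 15.70 days
simulated fraction pulse = 0.3719
estimated tau = 14.15 days (true: 14.00)
100 nuclei, median lifetime = 10.00 days (true: 10.00)
```

The first line converts a single measured fraction into a lifetime. The
simulation shows what a real experiment with a 14-day protein, dye at twice
the protein pool and an 82-minute effective clearance would measure: a
fraction slightly above e⁻¹ ≈ 0.368, because residual pulse ligand labels
some protein synthesized while it clears, biasing the estimate ~1% high.
The last line runs the full imaging pipeline — normalization, segmentation,
local background subtraction, micromolar calibration, lifetime conversion —
on a noisy synthetic image and recovers the true 10-day median lifetime.

See `docs/methods.md` for the models, defaults and their rationale.

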