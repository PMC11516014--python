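# paleodem

Multi-proxy archaeodemographic inference for Neolithic Southern Scandinavia
and comparable settings: relative population density from radiocarbon
dates, deposition intensity from typologically dated grave goods, and
human-induced landscape opening from pollen records — plus the time-series
statistics needed to compare the three proxies.

It is written for archaeologists and palaeoecologists who work with
"dates as data": the density of datable material in calendar time is read
as a proxy for the intensity of human occupation.

## What it computes

**Radiocarbon proxies.** A determination *d ± σ* is calibrated against a
curve *θ → (μ(θ), σ_c(θ))* by the Gaussian likelihood

    L(θ) ∝ exp( −(d − μ(θ))² / 2(σ² + σ_c(θ)²) )

evaluated on an annual calendar grid. From a filtered set of dates the
package builds

- the **SPD** (summed probability distribution), S(θ) = Σᵢ pᵢ(θ);
- **composite KDE models**: each of R simulations resamples the dates with
  replacement, draws one calendar year per date from its calibrated
  density, and smooths with a Gaussian kernel (bandwidth 50 yr); the
  ensemble mean and 2.5/97.5 % envelope separate demographic signal from
  sampling error and calibration artefacts (defaults R = 1000, bw = 50 yr);
- a **Monte Carlo exponential-null test**: the SPD is fitted by
  A·exp(λt), simulated datasets are drawn from the fitted null (forward-
  modelled through the curve with the empirical lab-error mix), and the
  observed SPD is compared against the simulation envelope, yielding
  boom/bust deviation intervals and a global p-value;
- **growth rates** g(t) = (K(t+w)/K(t))^{1/w} − 1 from the KDE ensemble.

**Aoristic sums.** An artifact typologically dated to a span [a, b] BCE
receives weight 1/(a−b+1) in each span year; summing across an assemblage
gives a deposition-intensity series per category (battle axes, flint
daggers) and region.

**Vegetation openness.** Terrestrial pollen proportions are ordinated by
PCA; PC1 separates forest from light-demanding taxa and is oriented so the
open-land indicators (grasses, heather, ribwort plantain) load positive.
Per-sample scores are interpolated record-by-record onto a 50-yr grid and
averaged into regional openness series.

**Cross-proxy statistics.** Linear detrending, 25/50-yr binning, Pearson
correlation over the standard windows (full 2850–1700, MNB 2850–2350,
LN 2350–1700 BCE), lagged cross-/auto-correlation, and event detection as
maximal runs with |z| ≥ k standard deviations (default k = 1).

A synthetic-data module generates all three data classes from known ground
truth (population trajectories forward-modelled to ¹⁴C ages; artifacts
drawn from a deposition curve; multinomial pollen counts from a
forest/open mixture), so every stage is testable without downloads.

## Worked example

```python
import numpy as np
from paleodem import (CalendarAxis, CompositeKDE, PopulationTrajectory,
                      simulate_dates, synthetic_curve)

axis = CalendarAxis(2850, 1700)          # observation window, years BCE
curve = synthetic_curve(wiggle_amp=15.0)  # identity-like curve with wiggles
traj = PopulationTrajectory.exponential(axis, 0.001)  # 0.1%/yr growth

dates, _ = simulate_dates(traj, 500, curve, rng=np.random.default_rng(1))
res = CompositeKDE(dates, curve, axis.pad(100), n_sim=500).fit(seed=2)
print(res.summary())
```

prints

```
Composite KDE model
----------------------------------------
dates:      500
axis:       2950-1600 BCE, step 1
bandwidth:  50 yr
ensemble:   500 simulations, bootstrap=on
envelope:   2.5/97.5 percentiles
mode (mean curve): 1858 BCE
```

The mode near the young end of the window is exactly what a 0.1 %/yr
exponential should produce; fitting a log-linear slope to the KDE mean
over the central window recovers the generating rate to within a few
percent (`scripts/acceptance.py` does this measurement from scratch).
The same objects expose `.growth()`, `.restrict()`, `.to_frame()` and
`.plot()`; `ExponentialNullModel(...).fit()` and `OpennessPCA(...).fit()`
follow the same model/results pattern.

A `paleodem` command line wraps the pipeline
(`spd | ckde | nulltest | aoristic | openness | correlate | events |
simulate | run`); `paleodem run --dates ... --curve ...` emits per-region
SPD/KDE/growth CSVs, event listings and cross-proxy correlation tables
with full provenance headers.

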