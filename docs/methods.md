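# Methods

This note documents the models implemented in `paleodem`, the choices that
were genuinely open, and what the synthetic-data tests do and do not show
about real archaeological data.

## Calendar conventions

All series live on an integer grid of years BCE that counts *down* toward
the present, so array index increases forward in time. Conversion to the
radiocarbon cal BP scale uses a single declared convention,
`cal BP = BCE + 1949` (1 BCE ↔ 1950 cal BP, no year zero), applied only at
the calibration-curve boundary. The default observation window is
2850–1700 BCE; density estimation pads it by ±100 years so kernel and
calibration mass is not truncated against the window edge, and results are
sliced back afterwards.

## Calibration model

A conventional age d ± σ is inverted through a curve θ → (μ(θ), σ_c(θ))
by evaluating, per grid year,

    L(θ) = exp(−(d − μ(θ))² / 2(σ² + σ_c(θ)²)) / √(2π(σ² + σ_c(θ)²)).

μ and σ_c are interpolated *linearly* between curve knots (IntCal-class
curves publish 5-yr knots in this era); this matters only in that any
independent check must interpolate the same way. Normalised mode rescales
to unit sum over the axis; unnormalised mode keeps raw likelihood heights
× grid step — the two produce visibly different summed distributions, and
both are exposed because the choice is a live issue in the field.
Densities losing > 0.1 % of their full-coverage mass to the axis raise a
truncation warning and are renormalised over the window.

The forward model (`uncalibrate`) draws a measured age from
Normal(μ(θ), √(lab_error² + σ_c(θ)²)). It powers both the synthetic
generator and the null test's simulated datasets.

## Source-critical filters

Before modelling, dates are filtered in a fixed order with a per-rule
audit: measurement error > 100 ¹⁴C yr; marine materials (shell) to avoid
reservoir offsets; calibrated median outside the padded window
(2950–1600 BCE). Each rule's removal count is reported so a dataset
summary table can be reconciled against the audit.

## Composite KDE model

Per simulation r of R (default 1000): (i) resample the n dates with
replacement (full-n bootstrap — the "subset" interpretation that yields a
proper sampling-error envelope); (ii) draw one calendar year per sampled
date from its calibrated density; (iii) kernel-density estimate with a
fixed Gaussian bandwidth of 50 years, renormalised to unit mass over the
padded axis. The ensemble is summarised by its pointwise mean and
2.5/97.5 % quantile envelope.

Numerically the per-simulation KDE is computed by binning the sampled
years on the annual grid and convolving with a Gaussian kernel truncated
at 6σ — exact on an integer grid to well below the envelope's Monte Carlo
noise, and what keeps a 1000-member ensemble cheap. With `boot=False`
only the calendar-year draw varies, isolating chronological uncertainty.

Growth rates are geometric annualisations over a sliding window w
(default 25 yr, matching the 25/50-yr binning used elsewhere):
g(t) = (K(t+w)/K(t))^(1/w) − 1, computed per ensemble row and summarised
by mean and envelope (a mean-curve-only mode exists for cheap scans).
Cells where K(t) ≤ 0 are masked rather than clipped.

## Exponential-null test

The observed SPD is fitted by least squares to A·exp(λt) on the window.
Each simulation draws n calendar years ∝ the fitted model, attaches lab
errors resampled from the observed error set, forward-models them to
measured ages, recalibrates and sums. Deviation intervals are maximal
runs where the observed SPD exits the 2.5/97.5 % simulation envelope. The
global p-value follows the standard dates-as-data model-test protocol:
per-year z-transform against the simulation mean/sd, statistic = summed
exceedance beyond the z-envelope, p = (1 + #{sim ≥ obs}) / (R + 1).
Empirically (400 replicates of data simulated from the fitted null,
n = 100 dates, R = 100) the test rejects at ≈ 6 % for a nominal 5 % —
the mild anticonservatism that comes from not propagating the fit's own
uncertainty, shared with the standard protocol.

## Aoristic sums

Spans are closed intervals of whole years; an artifact dated to [a, b]
BCE gets weight 1/(a − b + 1) per span year ("uniform probability to date
in one year of the span"), so total mass per fully-in-window record is 1.
Truncated spans keep their per-year weight (mass outside the axis is
lost, detectably). Only grave-context finds enter the default
comparison, since battle axes and daggers share a deposition pathway only
there. Typochronological spans per subtype are *editable configuration*
(`data/typochronology.yaml`): the axe/dagger literature anchors the LNI
(2350–1950 BCE) and LNII (1950–1700 BCE) dagger phases and the
2350–2250 BCE axe/dagger overlap, but per-subtype spans vary between
catalogues, so the shipped table is a documented assumption, not canon.

## Openness PCA

Counts are converted to proportions of the selected terrestrial taxa sum
(no transform by default; a √-transform switch exists), column-centred,
and decomposed by SVD. The PC1 loading vector is sign-fixed so the mean
loading of the open-indicator set (default: Poaceae, Calluna, Plantago
lanceolata) is positive — making the score's orientation reproducible
across platforms. The PCA window defaults to 4800–700 BCE, where the
forest/open taxa relationships are stable. Records can be flagged
`projection_only`: they receive scores but do not shape the loadings
(the treatment needed when a record lacks a key discriminating taxon,
e.g. missing beech). Diagnostics report PC1 variance explained and the
open-vs-forest loading separation, because in some regions (Scania-type
failure) the openness gradient simply does not project onto PC1 and the
score must not be interpreted.

Regional series: per record, scores are linearly interpolated onto a
50-yr grid *restricted to that record's own age span*; the regional
series is the unweighted mean across records per bin (bins with no record
are missing, not zero); optional smoothing is a centred 3-bin moving
average. Antagonistic records therefore cancel — a flat regional score
can mean either stability or spatially shifting activity, and the
per-bin record count is carried so users can tell.

## Cross-proxy statistics

Detrending subtracts an OLS line. Binning takes non-overlapping block
means labelled by midpoint, dropping (and reporting) a trailing partial
block. Pearson windows are full 2850–1700, MNB 2850–2350 and LN
2350–1700 BCE. Cross-correlation reports Pearson r at integer-bin lags
with the convention that a *positive* lag means the first series leads;
lags with < 3 overlapping points are undefined. Event detection z-scores
the series against its own window mean/SD and flags maximal runs with
|z| ≥ k; k defaults to 1.0 SD — SD rather than percentiles because
smoothed proxies (KDE means) have compressed variance; the multiplier is
exposed everywhere since no single value is canonical. Runs are split
where the sign flips. Neither detrended series nor growth rates are
stationary; the statistics are descriptive, not inferential.

## Synthetic data: what it emulates and what it does not

`simulate_dates` draws event years ∝ a population trajectory (constant,
exponential, logistic, piecewise boom-bust), forward-models each to a
measured age through the curve, and assigns site labels from a
k-category Dirichlet-multinomial (default 50 sites, concentration 1) to
mimic the clustering of dates on sites. Lab errors are fixed (default
40 ¹⁴C yr), uniform, or resampled from an empirical error column. The
default synthetic curve is identity-like with a configurable sinusoidal
wiggle (amplitude 15 ¹⁴C yr, period 300 yr, curve error 10 ¹⁴C yr) and an
optional flat plateau segment, so plateau artefacts can be reproduced on
demand.

`simulate_artifacts` assigns each drawn deposition year the narrowest
covering typology span; `simulate_pollen` mixes forest and open taxon
profiles by a known openness trajectory o(t) ∈ [0,1], draws multinomial
counts (default 300 grains/sample, 40 samples/record, 3 records) and
jitters sample ages by Normal(0, 25 yr) to mimic age-depth uncertainty.

Not emulated: taphonomic loss, research-history sampling bias,
reservoir-affected materials, pollen productivity differences and basin
source-area effects. Passing recovery tests on these generators shows
the *estimators* are correct and well-calibrated under their stated
assumptions; it does not show that real Neolithic datasets satisfy those
assumptions.

## Problem sizes and numerical choices

The test-suite and acceptance measurements use deliberately desk-scale
sizes chosen to keep each statistical check's Monte Carlo error well
inside its assertion band: growth-rate recovery at n = 500 dates /
500-member ensembles; boom localisation over 50 replicate datasets of
n = 800 with 50-member ensembles; null-test calibration over 200
replicates (n = 100 dates, 100 simulations each); lag detection over 50
replicate two-region scenarios of n = 600 dates per region (typical of
the regional datasets this class of study works with) with a 3×, 150-yr
boom. Ties in argmax-style reductions resolve to the earliest grid year.
Degenerate inputs (zero-variance series, constant proportion matrices,
all-zero densities, empty filters) raise explicit errors rather than
propagating NaNs.
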