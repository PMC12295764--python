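# Methods

## The measurement model

A probe trap's daily count is an indirect, activity-mediated sample of the
local insect population: catch rises with density but also with anything
that makes insects move (warmth, humidity). The package therefore treats
the 15 simultaneous daily counts of one bin as a *sample set* and
characterizes the population through statistics of those sets rather than
through any single trap.

Throughout, the sample variance uses the n−1 denominator (15 traps is a
small sample; the independent test oracles assume the same convention).

### Dispersion indices

For a sample set with mean x̄ > 0 and variance s², Lloyd's mean crowding is
I_L = x̄ + s²/x̄ − 1. Sets with x̄ = 0 have undefined crowding and are
excluded from the regressions *with an exclusion count carried into every
report* — an all-zero day is information about detectability, not a
nuisance to drop silently.

Two regressions summarize how crowding and variance scale with density:

* Iwao: I_L = b₀ + b₁·x̄ (ordinary least squares over sample sets). b₀ is
  the basic-component index (≈0 individual, >0 colony, <0 repulsion); b₁
  is the density–contagiousness coefficient (>1 aggregated, =1 random,
  <1 uniform).
* Taylor: ln s² = ln a + b·ln x̄ over the sets with x̄ > 0 *and* s² > 0
  (both logs defined). The slope b classifies dispersion the same way.

Exact equality of a fitted coefficient with 0 or 1 is measure-zero, so the
labels use a tolerance, default **0.05**, and the raw coefficients are
always reported beside the labels. The default reproduces all 18 published
pattern labels when fed the published coefficients, including the two
borderline values (b₀ = −0.06, b = 1.08); it is small enough that a
genuinely Poisson process still labels *random* only through its fitted
slope, not by construction.

Fits are computed per replicate bin across its sampling days and the
coefficients averaged across replicates (matching how replicate-mean
coefficients are conventionally reported); a pooled mode fits one
regression over all replicates' sets. By default all 10 days of a density
phase contribute one sample set each; a day-restricted mode (e.g. day 10
only) is available since the phrase "sampling days" admits both readings.
R² and point counts accompany every fit so pathological fits (e.g. a
two-point regression dominated by one outlying day) are visible.

### Spatial pair correlations

Counts from location pairs at a fixed lag are pooled over days (and
optionally replicates) and summarized by Pearson's r with its two-sided
p-value. The five lag classes follow from the deployment geometry: 30 cm
(center↔half-radius, 12 pairs), 42 cm = 30·√2 rounded (ring-adjacent
half-radii, 12 pairs), 60 cm (adjacent layers, 5 pairs), 120 cm
(top↔bottom, 5 pairs). Vertical pairs match identical planar positions
across layers — the only pairing compatible with fixed vertical
separations. Zero variance in a pooled coordinate yields an explicit
undefined flag (with n), not r = 0. Significance is starred at α ≤ 0.05 (*)
and α ≤ 0.01 (**).

### Condition effects

The factorial test regresses daily per-trap counts on four categorical
factors: density, MC, temperature binned at (0, 20, 25, 30, 40) °C and
humidity binned at (0, 50, 60, 70, 80) %RH, bins left-closed/right-open.
Main effects only, Type II sums of squares — the design is unbalanced and
no interaction structure is asserted. Out-of-range covariate values go to
the nearest outer bin and are counted in a warning (lossless and
auditable); single-level factors are dropped with a warning rather than
contributing a zero-DF row. In the emulated design the humidity bins are
strongly collinear with MC (dry bins sit near 43 %RH, moist near 62 %RH),
which genuinely depresses the MC partial F — the power property is
therefore tested on a configuration whose covariate regimes are equalized
across MC levels, isolating the planted factor.

Paired t-tests are two-sided with the pairing axis an explicit argument
(the natural pairing unit — days vs bins — depends on the comparison and
is not fixed here). Zero-variance differences return an undefined flag.

The density–trap-frequency analysis computes TF_D (trailing-window mean
daily catch, window anchored at the most recent day of the phase) per
location and phase, correlates TF_D with the introduced density across
phases — raw densities by default, log10 optionally — and averages r over
locations per window, per MC level and pooled. With three density phases
each correlation rests on few points; p-values are reported but the
location-averaged r per window and the best-window identification are the
intended outputs.

## The synthetic-data generator

The generator emulates the study design: 2 MC levels (10.7/14.0 %),
densities 0.1/1.0/5.0 adults/kg as consecutive 10-day phases, 3 replicate
bins at the dry level and 2 at the moist level, 15 traps per bin.

Counts are negative binomial with dispersion k = 2 (variance μ + μ²/k),
chosen as the simplest overdispersed integer law whose variance–mean curve
produces Taylor slopes strictly between 1 and 2 — the structure the
dispersion analyses must detect. The mean is log-linear:

    μ = β₀ · density^e · mc_factor · layer_weight · trend(day)
        · exp(γ_T·(T − T_base) + γ_RH·(RH − RH_base))

with defaults β₀ = 0.6 (per-trap daily count at density 1, dry, middle
layer, day 1), e = 0.7 (sub-proportional growth of catch with density, as
the published per-trap means suggest), mc_factor 3 at the moist level,
layer weights middle/bottom-heavy when dry and top-heavy when moist
(mirroring the published capture-percentage pattern), a declining trend
exp(−0.08·(day−1)) for dry bins and a zero-drift 5-day oscillation (±30%,
phased to rise within each cycle) for moist bins. Temperature and humidity
follow stationary AR(1) processes (ρ = 0.6) around 26 °C/43 %RH (dry) and
28 °C/62 %RH (moist) with sds 1.2 °C and 3 %RH — the covariate regime of
the monitored bins — and feed back into μ through γ_T = 0.05/°C,
γ_RH = 0.01/%RH.

Manual probe sampling is simulated as negative-binomial counts with mean
density × sample mass and a clumping parameter (large k ≈ Poisson).

What the generator does **not** model: mechanistic insect movement, trap
interference through semiochemicals, fungal stimulation of activity, or
seasonal drift — all plausible in real bins. Passing tests therefore
demonstrate that the pipeline recovers planted statistical structure
(overdispersion, layer preference, temporal trend, density–TF coupling)
from data of the right shape and magnitude, not that real infestations
behave like the generator.

Reproducibility: each (MC, replicate, density) cell derives its RNG stream
from the master seed via a fixed spawn key, so record sets are
byte-identical across runs and insensitive to generation order.

## Numerical choices and degenerate inputs

* OLS fits use statsmodels; classification thresholds apply *after*
  averaging coefficients across replicates.
* CP_L with a zero period total is reported as not-available (0/0 is not a
  percentage); detection summaries of an empty record set raise.
* A condition where no replicate yields two usable sample sets is reported
  as an unfitted condition with its reason, and the remaining conditions
  are still fitted.
* Dispersion accompanying reported means is the standard error over the
  stated pooling unit (trap-days for per-trap daily means, locations for
  TF summaries), labelled as such.
* Sub-daily trap uploads are assumed pre-summed to daily counts; the
  ingestion layer rejects duplicated (bin, day, location) keys rather than
  aggregating them.

## Problem sizes in the test and acceptance suites

Oracle equivalence uses 1 000 random small instances; Taylor-slope recovery
uses 200 sample sets with μ spanning one decade at k = 2; Poisson
classification uses 100 seeds × 200 sets; null calibrations use 200 seeds
(four factor tests each for the ANOVA; five lag classes each for the pair
correlations); the window-ranking check uses 50 simulated experiments.
These sizes give Monte-Carlo standard errors comfortably inside the
asserted bands while keeping a full run of suite plus acceptance script
under a minute of compute.

## Known limitations

* The three-density correlation design caps the density–TF analysis at
  3 points per location per MC level; the per-location coefficients are
  descriptive, not inferential.
* The ANOVA treats counts as a continuous response, as is conventional for
  this analysis; a count GLM would be the modern alternative but would not
  reproduce the published table structure.
* The pair-correlation p-values assume pooled pairs are independent;
  pairs sharing a trap (the 30/42 cm classes) violate this mildly, so
  those stars should be read qualitatively.
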