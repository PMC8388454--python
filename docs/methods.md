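# Methods

## Heat-stress exposure

The hourly temperature-humidity index uses the NRC dry-bulb form
`THI = (1.8·T + 32) − (0.55 − 0.555·RH)·(1.8·T − 26)`. The interface accepts
relative humidity in percent and converts to a fraction before substitution:
with the 0.555 coefficient the fractional form is the one that yields index
values in the established cattle heat-stress range (≈68–74 for a warm summer
barn), and `0.555·RH_frac` is numerically the standard `0.0055·RH_pct` term.
At `T = 26/1.8 ≈ 14.44 °C` the humidity term vanishes, so THI = 58 for any
RH; above that pivot humidity aggravates the index, below it it relieves it.

Hourly values pool all sensors: the mean temperature and mean RH over every
reading in the half-open clock hour `[t, t+1)`, with THI computed from those
means (not averaged over per-sample THI values). Timestamps are naive local
time.

**Heat load.** `THI_load(t)` sums the 24 hourly THI values strictly before
`t`. The exclusive window keeps the index causal for the hour it explains; an
inclusive variant is available (`include_current=True`). If any hour in the
window is missing, the load is undefined and the hour is excluded from all
downstream statistics. Hours are classified into THI_load quartiles —
boundaries either supplied by the caller or estimated as linear-interpolation
sample quantiles — with values exactly on a boundary going to the lower
group, matching the strict inequalities that define Q1 and Q4. Q1 is labelled
NS (no stress), Q4 HS (heat stress), Q2/Q3 intermediate. Note the quartile
scheme makes "stress" relative to the study period's own distribution, not an
absolute THI threshold.

## Behavior data model

Collars classify each second into one of six states and report minutes per
state per animal-hour, so states are treated as mutually exclusive minutes:
each in [0, 60] and summing to at most 60, with the remainder unclassified
time (e.g. milking-parlor absence). Fractional minutes are allowed.
"Activity" always means the mid + high aggregate; eating is its own state,
not part of activity. Rows violating the budget are rejected at parse time
and counted.

## Group comparison

NS vs HS behavior budgets are compared as a one-way fixed-effects ANOVA on
animal-hours, `y_ij = μ + τ_i + ε_ij`, computed from explicit sums of
squares with the p-value from the upper F tail. Animal-hours are treated as
independent — a deliberate simplification (no repeated-measures or
autocorrelation correction), inherited from the design this pipeline
implements; with the large n the analysis produces, p-values are anticonservative
and should be read together with effect sizes. With two groups the F test
equals Fisher's LSD and the squared pooled-variance t test, so no separate
post-hoc machinery exists.

## Circadian models

Two forms, fitted per behavior per stress group on all animal-hour points
(unweighted):

- single harmonic, period fixed at 24 h: `μ + a·sin(2π/24·h + b)`, 3
  parameters — for behaviors with one daily peak (rest, activity, heavy
  breathing);
- double harmonic with free periods: `μ + a·sin(2π/T₁·h + b) +
  c·cos(2π/T₂·h + d)`, 7 parameters — for behaviors whose daily pattern is
  punctuated by management events (eating, rumination). The form assignment
  is configuration, not inference.

All phases are stored as additive radian offsets. Since `(a, b)` and
`(−a, b+π)` describe the same curve, fitted parameters are reported both raw
and normalized (amplitudes ≥ 0, phases wrapped to (−π, π]); comparisons
against published equations should go through curve values, not raw
parameters.

**Estimation.** Nonlinear least squares (`scipy.optimize.least_squares`,
TRF) started from a deterministic brute-force grid:

- single: 16 phases `{0, π/8, …, 15π/8}` × amplitudes `{¼, ½, ¾, 1}` of the
  data half-range, μ pinned at the sample mean (64 candidates);
- double: all period pairs from 4–26 h in 0.5-h steps with `T₂ ≤ T₁` (to
  remove the sine/cosine relabelling symmetry), phases `{0, π/2, π, 3π/2}`
  per wave, both amplitudes at half the data half-range (≈16,560 candidates).

Candidate RSS is scored on per-unique-hour sufficient statistics (counts and
means), which is exact for least squares and makes the grid cost independent
of the number of animal-hours. Ties break toward the smaller period, then the
smaller phase, so the search is fully deterministic. The refinement uses
`ftol = 1e−10`, `xtol = 1e−8`, at most 500 iterations, with free periods
bounded to [2, 48] h (2 h is the Nyquist period of hourly sampling; see
limitations); if the optimizer ever ends above the grid start's RSS the start
is returned with `converged = False`, so refinement is monotone by contract.

**Scoring.** `R² = 1 − RSS/TSS` and `R²_adj = 1 − ((n−1)/(n−p))(1−R²)`; both
are reported, with the adjusted version the headline goodness-of-fit.
Pointwise standard-error bands for fitted curves come from the delta method
on the linearized parameter covariance `σ̂²(JᵀJ)⁻¹` at the optimum — an
interpretation choice, since "modelling error" bands admit several readings.

**Daily means.** `model_mean` averages a model on a uniform grid of ≥ 1440
points over [0, 24). For the single form the harmonic sums to zero on any
uniform full-period grid, so the daily mean equals μ to floating-point
precision; free-period double harmonics do not integrate to zero over one
day, so their daily mean differs from μ (e.g. the reference no-stress
rumination model averages 23.71 against μ = 23.13).

**Pattern summaries.** Peaks and troughs are located on a 1-minute grid,
merging extrema within 10 minutes and discarding extrema whose prominence is
below 10% of the curve's daily range — a dominant-wave ripple from a small
fast harmonic is not a differentiated peak (observed prominence fractions in
the reference models separate cleanly: ≥ 0.28 for real peaks, ≤ 0.05 for
ripple). Detection wraps across midnight only for the strictly 24-h-periodic
single form; free-period models are summarized over [0, 24) as fitted,
without enforcing wrap continuity.

## Synthetic farm generator

The generator exists so every stage is testable without proprietary collar
data. What it emulates, and what it deliberately does not:

**Environment.** A diurnal temperature cycle spanning the configured
min/max (defaults 13.8–33.2 °C, a Mediterranean summer) peaking at 15:00,
with RH in anti-phase around its mean (default 50%, amplitude 15%). The
cycle is centred on the min/max midpoint (23.5 °C) so the stated extremes
are hit exactly; the configured mean (23 °C) is honored to 0.5 °C. The curve
is step-constant within each clock hour, so noise-free hourly means equal
the curve exactly. On top: per-day offsets — optional heatwave episodes
(default +5 °C over days 7–13 of a 14-day study) plus Gaussian day-to-day
variation (sd 1 °C, without which THI_load is near-constant within weather
blocks and quartile boundaries degenerate to sensor noise) — and independent
Gaussian sensor noise (sd 0.3 °C, 2% RH) per 5-minute reading on each of the
15 sensors. The temperature peak at 15:00 aligns the simulated THI maximum
with the observed afternoon panting peak.

**Behavior.** Each animal-hour draws the five modelled behaviors from the
stress regime of its hour (NS model, HS model, or their midpoint for
intermediate/undefined hours — the reference study never modelled Q2/Q3
behavior) plus independent Gaussian noise (sd 5 min), truncated at 0;
activity is then split 73%/27% into mid/high (the real split is unpublished;
this is a configurable stand-in), and if the six states exceed 60 minutes all
are rescaled proportionally onto the budget. Truncation-then-rescale
preserves non-negativity and the hour budget simultaneously. Consequences to
keep in mind: truncation inflates low-mean behaviors (heavy breathing under
NS) and the budget rescaling shrinks all behaviors in busy hours, so
full-generator group means sit slightly off the generating μ values — the
generator reproduces the NS/HS *ordering* of every behavior, not the exact
reference means. For parameter-recovery experiments use
`sample_from_model`, the idealized mode (model value + Gaussian noise, no
truncation), where the generating parameters are exactly the least-squares
estimands.

Not simulated: milking-parlor absences as a distinct state, cooling
interventions, pen spatial structure, per-cow heterogeneity in circadian
parameters, and autocorrelated weather beyond the day offsets. Passing tests
on synthetic data therefore demonstrate the pipeline's statistical machinery
and directionality, not field performance on real barns.

**Scale and determinism.** The default study is 15 sensors × 288
readings/day and 40 animals × 24 h over 14 days (60,480 sensor rows, 13,440
animal-hours) — the scale the analysis was designed around, and small enough
that the full pipeline runs in seconds. Every stochastic routine takes an
explicit seed or `numpy` Generator; a fixed seed reproduces all artifacts
byte-for-byte.

## Known limitations

- With hourly sampling, harmonic periods below 2 h are beyond the Nyquist
  limit and alias exactly onto longer periods; the reference heat-stress
  rumination model contains such a wave (period 1.808 h, amplitude 0.386),
  which is therefore not recoverable from data generated at the study's
  sampling design — only its dominant 11.22-h wave is identifiable.
- At the per-animal-hour level, behavior noise of sd 5 min bounds attainable
  R² well below what fits on hourly *means* would show (e.g. a 2.5-min
  amplitude gives R² ≈ 0.11); fitted parameters are nonetheless recovered
  tightly because n is large.
- The quartile scheme adapts to each dataset's heat-load distribution;
  NS/HS labels from different studies are not directly comparable.
- ANOVA independence, as noted above, ignores within-animal and within-hour
  correlation.
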