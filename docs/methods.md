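# Methods

This note documents the models, conventions and numerical choices behind
`sealdive`, and what the synthetic generator does and does not emulate.

## Trace processing

**Zero-offset correction.** Pressure transducers drift slowly, so raw
surface readings wander away from 0 m. The correction estimates the
surface offset with a two-pass running low-quantile filter: a 5 % rolling
quantile over a short centred window (default 5 min) picks up local
surface readings between dives; a second 5 % rolling quantile over a long
window (default 2 h) smooths that estimate across dive bouts. The offset
is subtracted and negative depths clamped to zero. The approach follows
the standard practice of dive-analysis software; windows and quantile are
parameters. With Gaussian sensor noise of sd 0.2 m, the low quantile sits
roughly 1.6 sd below the true surface, leaving a residual bias of ~0.3 m;
corrected depths track truth with RMSE < 0.5 m under ±2 m/day drift. The
filter is idempotent up to clamping.

**Trips.** A trip is a maximal wet interval of the conductivity channel;
dry spells shorter than `min_dry` (default 10 min — wet/dry sensors
chatter) are bridged. Trip duration (TD) is reported in days.

**Dives.** A dive is a maximal run of samples deeper than a surface
epsilon (0.5 m, below which sensor noise dominates) whose maximum depth
strictly exceeds the threshold (default 4 m; shallower excursions are
travelling/wave artefacts, not foraging). "Greater than 4 m" is read
strictly; an excursion to exactly 4.0 m is not a dive. Dive boundaries are
half-open sample intervals `[start, end)`, which makes the phase partition
and post-dive-interval arithmetic exact. A dive must span at least 3
samples (descent, apex, ascent support at 5 s sampling).

**Phases.** The bottom phase runs from the first to the last crossing of
75 % of maximum dive depth; descent precedes it, ascent follows. The three
half-open intervals partition the dive, so phase durations sum exactly to
dive duration. A V-shaped spike yields a bottom phase of one sample.

## Shape classification

Each dive receives exactly one label with precedence
PURSUIT > BENTHIC > V > U (a pursuit dive may end near the seafloor, and a
V spike has no bottom phase to test for flatness). The thresholds are not
dictated by any instrument convention and are all configurable:

| parameter | default | meaning |
|---|---|---|
| `v_bottom_frac_max` | 0.10 | V if bottom-time fraction is below this |
| `pursuit_reversal_min` | 5 m | minimum ascent before the re-descent |
| `pursuit_deepen_min` | 0.25 | second nadir ≥ 1.25× the first |
| `pursuit_rate_ratio_min` | 1.2 | second/first descent-rate ratio |
| `benthic_cv_max` | 0.05 | CV of near-bottom depths within a dive |
| `benthic_seq_tol` | 0.10 | depth tolerance across adjacent dives |
| `benthic_seq_n` | 3 | run length implied by the adjacency rule |
| `benthic_flat_frac` | 0.90 | near-bottom = samples ≥ 90 % of max depth |
| `benthic_flat_cover_min` | 0.60 | near-bottom share of the bottom phase |

The pursuit rule finds the deepest reversal before the final nadir (the
largest ascent from the running maximum depth), and requires the reversal
height, the deepening factor and the descent-rate ratio to clear their
thresholds; rates are computed from in-dive depth differences because the
first sample is already submerged. The benthic rule tests flatness on the
near-bottom samples rather than the whole 75 %-of-max bottom phase — on
deep dives the phase includes descent/ascent ramp samples that would
otherwise dilute the CV — and additionally requires the near-bottom
samples to make up most of the bottom phase, which rejects pelagic U dives
whose ragged (school-chasing) bottoms would pass a CV test by selection.
Depth consistency is checked against the `benthic_seq_n − 1` nearest dives
on each side, making the rule symmetric under sequence reversal.

**Diel class** is assigned from the dive start time (dives are short
relative to twilight) against the half-open night window `[dusk, dawn)`;
a dive starting exactly at dawn is a day dive. Civil twilight (sun
altitude −6°) is computed from the standard NOAA solar-position equations
(Julian-century ephemeris; accurate to well under a minute, and verified
against an independent Spencer-series ephemeris to within 2 min). Fixed
clock times may be supplied instead for exact reproducibility.

## Effort metrics

Dive rate DR = Σ(2·MDD)/TD in m h⁻¹ (every metre descended is ascended);
TD is the full wet/dry trip duration, not time in dives. Because per-seal
depth and duration distributions are strongly right-skewed, trips are
summarized by modal, median and maximum statistics; modes use histogram
bins anchored at zero (defaults 0.5 m and 0.1 min, matching the 0.1
precision modes are conventionally reported at), ties breaking toward the
smaller bin. BCI is the residual (kg) of the cohort OLS regression of
body mass on standard length — mass-for-length. The regression direction
is a convention choice: the phrase "regression between length and mass" is
direction-ambiguous, and published per-seal BCI values for this population
cannot be reproduced by either direction; the package documents and uses
mass-on-length.

## Behavioural aerobic dive limit

Dives beyond the aerobic limit accumulate lactate and inflate the
subsequent surface interval. The estimator grid-searches a breakpoint over
observed durations between the 50th and 99th percentiles (capped at 40
candidates, ties to the smaller duration), fits first-percentile quantile
regressions of PDI on duration below and above each candidate, and picks
the candidate minimizing the summed check loss; the bADL is the duration
at which the two lines intersect. The first percentile tracks the lower
envelope of the scatter, so long waiting times at the surface (resting,
searching) do not bias the fit. The estimate is flagged ineligible — "no
clearly extended recovery structure" — when fewer than `min_dives`
(default 200) pairs exist, when the above-breakpoint slope is below 0.2
s/s or less than 3× the below-breakpoint slope, or when the intersection
falls outside the observed range. The absolute slope floor is what keeps
pure-noise scatters ineligible even when the below slope is ~0. On
synthetic data the estimator recovers the planted limit to well under 1 %
at n = 1000 dives.

## Body oxygen stores

Total stores (ml O2 per kg) are the sum of three components:

- **blood**: the arterial fraction (0.33) of blood volume releases
  Hb-bound oxygen (1.34 ml O2/g) between initial (0.95) and final (0.20)
  saturations; the venous fraction (0.67) carries arterial content at
  initial saturation minus a 5 vol% deficit (clamped at zero for
  degenerate Hb);
- **muscle**: Mb (g/100 g wet muscle) × 1.34 × muscle mass (30 % of body
  mass);
- **lung**: otariid diving lung volume 0.10·mass^0.96 litres, of which
  15 % is usable oxygen.

Blood volume derives from Evans-blue plasma volume and haematocrit,
Bv = Pv/(1 − Hct). Plasma volume comes from turbidity-corrected absorbance
(A624 − k·A740, k = 1 by default), a linear dye calibration, and
log-linear back-extrapolation of the clearance curve to the injection
time: Pv = dose/C0. These constants are configuration
(`PhysioConstants`), not code: the literature lineage they descend from
reports slightly different values across species and studies. With the
defaults, recomputed per-seal totals for the nine-seal chemistry panel
agree with the published per-seal totals to within 3.2 % (tolerance 5 %),
and DMR = mean stores / mean bADL reproduces the published 11.2
ml O2 kg⁻¹ min⁻¹.

## Statistical layer

All-subsets OLS model selection uses AICc with the parameter count k
including the intercept and the residual variance (intercept-only model
has k = 2). Models within ΔAICc ≤ 4 of the best are retained; Akaike
weights are renormalized over that set. Model averaging is the *full*
average: absent terms contribute zero (the alternative, conditional
averaging, is a switch away in the code but full averaging is the
default because it shrinks weakly supported terms toward zero).
Unconditional standard errors combine within-model variance and
between-model spread, `se = Σ w_i sqrt(se_i² + (β_i − β̄)²)`. Relative
importance is the summed weight of retained models containing the term.
The nested-model LRT uses `n·ln(RSS_small/RSS_large)` against chi-squared.

Clustering standardizes each per-seal feature (trip duration, modal dive
duration, modal depth, dive rate, % nocturnal, % benthic) by its column
total — "standardized by the total" is read as division by the column sum;
division by the maximum is available via `normalizer="max"` — then applies
group-average-linkage agglomerative clustering on Euclidean distances and
cuts at k = 2. Group-average linkage is the convention of the multivariate
ecology software family this analysis style comes from; it is a parameter.
Mann–Whitney comparisons use the exact null distribution for group sizes
≤ 8 (verified against full enumeration of rank assignments).

## Synthetic generator

The generator is the package's study-conditions stand-in for raw logger
data, which are not publicly deposited. Defaults encode the observed
conditions: 5 s sampling; a cohort shape mixture of 53.1 % U, 13.4 % V,
17.1 % pursuit, 16.4 % benthic; a true ADL of 231 s; trips of a few days
with night-heavy, crepuscular-peaked dive rates averaging ~8 dives/h
(no per-hour rates are published, so the diel weight *shape* is a module
default); benthic depths pinned to a fixed seafloor (default 150 m);
post-dive intervals `base + slope·max(0, duration − ADL) + lognormal
noise` (base 60 s, slope 2 s/s) acting as a recovery floor below which the
next dive cannot start; linear transducer drift (default 1 m/day, up to
±2 m/day in tests) plus Gaussian sensor noise (sd 0.2 m). Dive timing is
an inhomogeneous Poisson process (thinning) with the recovery floor
enforced sequentially, so realized post-dive intervals are
`max(recovery floor, waiting time)` — the first-percentile envelope the
bADL estimator reads is the floor. Shapes repeat with probability 0.7
(bout structure: benthic dives occur in runs over level bathymetry, which
the benthic adjacency rule requires); repeats preserve the marginal
mixture but inflate its sampling variance by roughly (1+ρ)/(1−ρ).

Deliberate idealizations: horizontal movement, temperature, tides and
swell are absent; the seafloor is flat; V dives are constructed as spikes
(shoulders at 60 % of max depth, a single apex sample) so that the
bottom-fraction rule can separate them at 5 s sampling; pelagic U bottoms
are ragged (uniform 78–100 % of max) where benthic bottoms are flat
(CV < 2 %). Passing tests therefore demonstrate that the pipeline
recovers the structure this generator plants — counts, depths, durations,
gaps, labels, the planted ADL and the planted two-strategy population —
not that it would be robust to every artefact of field data (e.g.
haul-out-adjacent surface swimming, thermoclines misread as dives, or
benthic foraging over sloping bathymetry).

Population archetypes for clustering validation: a night-active epipelagic
forager (shallow U/V dives, 3 % benthic) and a day-active benthic forager
(75 % benthic mixture, very low night rates, deeper seafloor). Their
six-feature summaries are computed directly from truth tables for speed.
A fixed seed reproduces traces and truth byte-identically.

## Numerical conventions and degenerate inputs

Histogram modes are deterministic given bin width (ties to the smaller
bin). Empty trips yield summaries flagged `defined=False` rather than
errors; too few dives for the bADL yield an ineligible estimate rather
than an exception. Overlapping dives, never-wet traces, non-positive
thresholds, constant predictors, zero column totals and out-of-range
haematocrits are rejected with `ValueError`. Quantile regressions use
statsmodels' iteratively reweighted least squares with a 200-iteration
cap; convergence warnings on degenerate subsets are suppressed and the
check-loss objective decides between candidates. Problem sizes in tests
(3-day trips, ~300 dives; 1000-dive bADL samples; 100-seal recovery
sweeps at 300 dives each; 32-seal populations) were chosen to keep the
full suite under a minute while leaving the statistical checks
well-powered.
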