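# Methods

This note documents the models and procedures `mobiphen` implements, the
parameters that matter, what the synthetic cohort generator does and does
not emulate, and the numerical and design choices made where the underlying
methodology left them open.

## Day boundaries and time

All day assignment uses a single fixed UTC offset per cohort (default −6 h,
a central-US winter offset), not per-point timezone lookup.  Study cohorts
of this kind are single-region, and a fixed offset keeps day partitioning
deterministic and reproducible; daylight-saving transitions shift the
nominal day boundary by an hour, which is immaterial for half-hour binned
features.  The offset is a parameter of every day-aware function and of the
CLI (`--utc-offset`).

## Displacement profiles

A participant-day is divided into 1440/`bin_width` bins (48 half-hour bins
for profiles, 96 quarter-hour bins for circadian analysis).  An observed
bin holds the arithmetic mean of its pings' latitudes and longitudes —
adequate at city scale and far from the antimeridian; no spherical
averaging or accuracy weighting is attempted.  Exactly duplicated records
(identical time and coordinates) are dropped before averaging so a
device-side duplicate cannot double-weight a bin.

Unobserved bins carry the most recent available coordinate forward.  Carry
crosses day boundaries: each day's leading gap is seeded with the previous
day's last known coordinate, and a participant's very first day backfills
from its own first observation (so leading displacements are zero).
Calendar days with no data at all still occupy the grid, fully carried
forward; the period therefore forms one unbroken bin sequence, and the
displacement series over D days has exactly D·bins − 1 entries.

Distances are haversine with Earth radius 6,371,000 m.

A day enters the PCA matrix only if at least half its 48 bins were observed
(`min_coverage = 0.5`, configurable and recorded in run manifests); the
duty cycle at default dropout leaves coverage near 0.8, so the filter
removes only heavily dark days.  PCA consumes raw displacements in meters —
log-transformed profiles are a visualization device, not the analysis scale
— is centered but not scaled, and uses a deterministic sign convention
(each loading's largest-magnitude entry is positive).  PCA is always fitted
on the pooled two-cohort matrix so component scores are comparable across
groups.

## Circadian metrics

IS, IV, M10, L5 and RA are computed on the participant's 15-minute
displacement series over the whole study period (one value per participant,
not per-day averages: IS is undefined for a single day, and the period-level
convention matches actigraphy practice).  The series is aligned to local
midnight; since displacement i is the transition *into* bin i+1, the series
carries a one-bin alignment offset.

- Hourly means X̄ₕ pool all days' samples for hour-of-day h.
- M10/L5 windows slide over the across-days average daily profile and wrap
  midnight.  Window means are computed directly per window (not via
  cumulative sums) so a flat profile yields M10 = L5 to the last bit and
  RA = 0 exactly; a one-ulp inversion from unequal window widths is
  tolerated and treated as equality.
- RA for a completely still participant (M10 + L5 = 0) is defined as 0.
- Constant series make IS and IV undefined (zero variance) and are
  signalled, not silently zeroed.

Under exchangeable noise the expected IS is ≈ (1 − 1/24)/(D·bins_per_hour)
— each hourly mean pools D·bins_per_hour samples — reducing to the familiar
≈ 1/D only for hourly binning.  The tests check both regimes against
brute-force evaluation of the defining formulas.

## Significant places and daily phenotypes

Stay detection is greedy temporal clustering: a candidate cluster grows
while each next point lies within `d_thresh_m` (default 75 m) of the
running centroid, and commits as a stay when its time span reaches
`t_min_s` (default 600 s).  Committed stays merge into places when their
centroids fall within `merge_thresh_m` (default 100 m).  The defaults sit
comfortably above GPS jitter (~10 m) and below typical inter-place
distances (hundreds of meters to kilometers); they are config-exposed and
recorded in output metadata.  The procedure is deterministic.

Home is the place with maximal pooled 00:00–06:00 dwell over the whole
period; a participant with no night-time dwell has no home and their
`perc_home` is missing rather than guessed.

Feature conventions, where alternatives exist:

- `perc_home` divides by *labeled* time (stays + transit, i.e. the span
  covered by the trace) so duty-cycle gaps do not deflate it; a wall-clock
  denominator is available (`denominator="wallclock"`).  Stays interpolate
  across ping gaps, so the ratio is capped at 100.
- `num_pls` counts distinct places visited that day (a place spanning
  midnight counts for both days), not stay visits.
- `loc_var` is √(var x + var y) of locally (equirectangular) projected
  coordinates, in meters; translation invariance is approximate at the
  0.1% level, which is inherent to local projection.
- `ent_pls` is Shannon entropy of dwell shares normalized by ln K, defined
  as 0 for a single place.
- `routine_idx` compares 30-minute-slot modal place labels across days:
  day d's index is the mean over slots of the fraction of other days with
  the same label in that slot, with "in transit / unlabeled" compared equal
  to itself.  The slot width and modal-label convention are this package's
  concrete instantiation of a routine measure that is usually described
  only loosely.
- `max_dist` is the exact O(n²) maximum pairwise distance (chunked), never
  a convex-hull or sampling heuristic.

## Synthetic cohorts

The generator plants known structure for the pipeline to recover.  Each
participant gets a home (scattered ~2.5 km around a city center) and a
Poisson-distributed number of anchor places, clustered in a 120° sector at
gamma-distributed distances (mean `anchor_dist_m` = 1,500 m) — errands tend
to cluster on one side of home, which also keeps inter-anchor hops short.
A day is either fully home-bound or contains a single excursion: departure
and return times are drawn from a 48-slot time-of-day intensity profile
(return at least `min_away_s` = 4 h later), the excursion visits
1 + Poisson(0.35·(n_places − 1)) distinct anchors in sequence with
straight-line transits at `trip_speed_mps` = 5 m/s, and each stop dwells at
least 10 minutes.  The probability of leaving home at all is scaled so the
long-run home-time fraction tracks `home_fraction`; the expected
departure-to-return gap is computed exactly by enumerating slot pairs.

Two presets encode contrasting routines: `pre2020` (n_places = 3, movement
peaks 8–10 a.m. and 7–9 p.m. with weight 1.0 against a 0.02 awake-time
background, home_fraction = 0.55) and `mid2020` (n_places = 1.5, flat
10 a.m.–6 p.m. profile, home_fraction = 0.80).  The sharp peak-to-background
ratio makes the bimodal preset genuinely bimodal: over many days ≥ 60% of
transit seconds fall inside the two peak windows.

Sensing is emulated as the duty cycle "scan 60 s of every 600 s":
`pings_per_scan` = 3 pings at uniform offsets inside each surviving scan
window, whole cycles dropped i.i.d. with `dropout_prob` = 0.2, and
isotropic Gaussian position noise with `jitter_sd_m` = 10 m.  Not emulated:
road networks, indoor/urban-canyon error inflation, battery-correlated or
diurnal dropout, device heterogeneity.  Passing tests therefore show the
pipeline recovers structure under honest burst sampling and noise, not that
it is robust to every real-world GPS pathology.

One momentary sadness prompt is emitted per participant-day at a uniformly
random minute between 09:00 and 21:00 local (a waking-hours prompt window;
real prompt cadence and compliance are study-specific and not modeled).
The severe-sadness probability is

    P(severe) = expit(beta0 + Σ_f beta_f · z(feature_f) + u_participant),

with u ~ N(0, sigma_u²) (default 0.5) and z-scores standardizing the
generator's *noise-free* mobility features across all participant-days.
The features entering the coupling are computed over the 24 hours preceding
the prompt — the same window the prediction layer observes.  Coupling the
label to the observable window (rather than to the calendar day) is what
makes a planted coefficient a recoverable effect: a calendar-day coupling
leaves much of the signal outside any pre-report window for morning
prompts.  Calendar-day noise-free features are still recorded in the
ground-truth log (`ground_truth.csv`), alongside the window features
(`win_*` columns), u, and the per-report severe probability.  All
randomness descends from one `SeedSequence`; identical configs and seed
reproduce the cohort byte for byte.

Default cohort sizes follow the two-group design the presets emulate
(20 participants per group, 21 days); the heavier simulation-based checks
use 16 participants × 14 days per cohort and 20 seeds, sizes chosen to make
seed-to-seed means stable at desk scale.

## Group comparison and prediction

The primary unit of analysis for Welch tests is the participant: day-level
scores and phenotypes are averaged per participant first, avoiding
pseudo-replication from within-person correlation.  Day-level pooling is
available (`unit="day"`) as a mirror of analyses that treat days as
independent.  Raw p-values are primary; a Benjamini–Hochberg column is
always emitted.

The mixed logistic model is a random-intercept-per-participant Bayesian
GLM fitted variationally (statsmodels).  Its primary AUROC marginalizes the
random effect — scores are the population-level linear predictor Xβ — with
the conditional AUROC (adding posterior-mean intercepts) reported
secondarily; an in-sample marginal AUROC on a null cohort sits slightly
above 0.5 purely from fit optimism, shrinking with rows per feature.

The random forest (500 trees by default, √p features per split, fixed
seed) is evaluated with leave-one-participant-out cross-validation: all of
one participant's reports are held out, the forest trains on everyone
else, and AUROC is computed per held-out participant when both classes are
present (participants with one-class outcomes are skipped and counted).
The reported statistic is the mean ± SD of per-participant AUROCs, which
measures *within-person* discrimination: between-person differences cannot
inflate it, so its ceiling is set by within-person variation in the coupled
features and the Bernoulli noise of the labels.  Simulation-based checks
use 200 trees, which is past the point of diminishing returns at these
data sizes.

## Known limitations

- Centroids and `loc_var` use flat-earth approximations; do not use near
  poles or the antimeridian.
- Carry-forward fabricates stillness through sensing gaps; long outages
  bias displacement-based metrics toward zero.  The coverage filter guards
  the PCA input but circadian series intentionally keep carried bins so the
  grid stays unbroken.
- The routine index depends on the slot width and modal-label choice;
  other instantiations (e.g. distance-based day similarity) would order
  days differently.
- The generator's one-excursion day template cannot produce overnight
  absences, commuting loops with midday returns, or multi-day trips.
- Mixed-logistic AUROC is in-sample unless the caller cross-validates;
  both conventions exist in the literature and both are exposed.
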