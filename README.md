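# mobiphen

Intradaily mobility phenotyping from duty-cycled smartphone GPS.

Smartphone sensing studies in digital mental health collect burst-sampled
GPS ("scan for 1 minute, pause for 10") from participant cohorts and ask
two questions: *how do daily movement routines differ between groups*, and
*does a person's recent mobility predict their momentary mood*?  `mobiphen`
implements the full analysis chain for those questions, together with a
seeded synthetic cohort generator so every stage can be exercised and
validated without access to restricted participant data.

## What it computes

**Daily Displacement Profiles (DDPs).**  Each participant-day is placed
into 48 half-hour bins; each bin holds the mean coordinate of its pings
(empty bins carry the most recent known position forward).  Differencing
adjacent bin centroids with the haversine distance gives a 47-vector of
displacements — the day's movement signature.  Principal component analysis
of the pooled DDP matrix yields interpretable time-of-day movement modes
whose scores are compared between groups.

**Nonparametric circadian-rhythm metrics** on the 15-minute displacement
series X₁…Xₙ over the study period:

- IS (interdaily stability) = [Σₕ (X̄ₕ − X̄)²/24] / [Σᵢ (Xᵢ − X̄)²/n], with
  X̄ₕ the mean over hour-of-day h pooled across days;
- IV (intradaily variability) = [Σᵢ₌₂ (Xᵢ − Xᵢ₋₁)²/(n−1)] / [Σᵢ (Xᵢ − X̄)²/n];
- M10 / L5: mean of the average daily profile over its most active 10
  consecutive hours / least active 5 consecutive hours (wrapping midnight);
- RA (relative amplitude) = (M10 − L5)/(M10 + L5).

**Seven daily digital phenotypes** built on significant-place clustering
(greedy temporal stay detection, then centroid merging): location variance,
number of places visited, normalized entropy of time across places, percent
of time at home (home = the place with most pooled 00:00–06:00 dwell),
total distance, maximum pairwise distance, and a routine index measuring
how similar a day's time-slotted place sequence is to the participant's
other days.

**Inference.**  Welch *t*-tests (Satterthwaite degrees of freedom) compare
the first 10 PC scores, the 5 circadian metrics and the 7 phenotypes
between two cohorts (per-participant means by default, with a
Benjamini–Hochberg column).  Severe-sadness prediction recomputes the seven
phenotypes over the 24 h preceding each momentary self-report (participants
with ≥ 2 severe reports retained) and evaluates (a) a random-intercept
logistic model and (b) a random forest with leave-one-participant-out
cross-validation, reporting per-participant AUROC mean ± SD.

## Worked example

Simulate two 8-participant, 10-day cohorts from the shipped presets —
`pre2020` (three anchor places, morning/evening movement peaks, less time
at home) and `mid2020` (one to two places, flat midday movement, more home
time) — extract features and compare:

```python
import dataclasses
from mobiphen import synthetic as syn, analysis

pre = dataclasses.replace(syn.PRESETS["pre2020"], n_participants=8, n_days=10)
mid = dataclasses.replace(syn.PRESETS["mid2020"], n_participants=8, n_days=10)
fa = analysis.extract_cohort_features(syn.simulate_cohort(pre, seed=1).traces)
fb = analysis.extract_cohort_features(syn.simulate_cohort(mid, seed=2).traces)
tab = analysis.compare_groups(fa, fb)
print(tab[tab.metric_name.isin(["IV", "RA", "num_pls", "perc_home"])])
```

which prints (columns abridged):

```
metric_name     mean_a     mean_b     t_stat    p_value
         IV      1.883      1.754      2.311    0.04332
         RA     0.7803     0.5329      1.747     0.1217
    num_pls      2.513        1.7      3.541   0.005417
  perc_home      55.97      87.03     -7.922  5.693e-05
```

The planted contrast is recovered: the home-bound `mid2020` cohort visits
fewer significant places per day (1.70 vs 2.51), spends far more time at
home (87% vs 56%), and shows lower intradaily variability and relative
amplitude.  `mean_a`/`mean_b` are per-participant means for the first and
second cohort; `t_stat` is signed as `mean_a − mean_b`.

The same pipeline is scriptable from the shell:

```sh
mobiphen --seed 1 simulate out/pre --preset pre2020
mobiphen --seed 2 simulate out/mid --preset mid2020
mobiphen extract out/pre/gps out/feat_pre
mobiphen extract out/mid/gps out/feat_mid
mobiphen compare out/feat_pre out/feat_mid out/cmp
mobiphen --seed 1 predict out/pre/gps out/pre/surveys.csv out/pred
```

Every stage writes a `manifest.json` with its config, seed and output
digests, so a run is reconstructible from the manifest alone.

## Layout

- `mobiphen.io_gps` — GPS/survey CSV dialects, validation, day partitioning
- `mobiphen.synthetic` — seeded cohort generator (regimes, duty cycle, mood coupling)
- `mobiphen.displacement` — binning, DDPs, displacement series
- `mobiphen.circadian` — IS, IV, M10, L5, RA
- `mobiphen.phenotypes` — significant places and the seven daily features
- `mobiphen.analysis` — PCA, Welch battery, mixed logistic, LOPO random forest
- `mobiphen.cli` — the `mobiphen` command

See `docs/methods.md` for the modeling assumptions, parameter defaults and
known limitations.
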