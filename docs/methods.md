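# Methods

This note documents the models and estimators in `ingestphase`, the
assumptions behind them, and the design choices made where the analysis
conventions in this area leave the details open.

## The analysis model

Ingestion-driven neural responses are analysed in three stages anchored to
behavioural events:

| stage | anchor | window (imaging) | window (photometry) |
|---|---|---|---|
| oral | start of first lick bout | 30 s | 30 s |
| gastrointestinal | intragastric infusion start | 0–12 min | 0–12 min |
| systemic | infusion start or first-bout start | 12–32 min | 12–50 min |
| systemic (IP) | intraperitoneal injection | 0–30 min | 0–30 min |

A *lick bout* is a maximal run of licks spanning ≥10 s in which no inter-lick
interval exceeds 2 s; "spanning" is read as first-to-last lick time, and a
gap of exactly 2 s stays inside a bout. The baseline epoch is the 10 min
preceding the anchor.

Two epoch presets are provided because the field has used both conventions:
`start_anchored` (above) and `legacy_end_anchored`, which instead scores a
post-ingestion window 0–20 min after consumption or infusion *ends*. Reports
always carry the preset name; the two are never merged.

### Normalization

Traces are z-scored against the baseline: `z = (raw − μ)/σ` with μ and the
population standard deviation σ (divide-by-n; the convention is not fixed in
the field, so one estimator is fixed here for reproducibility) computed over
the baseline window. Neurons with zero baseline variance are excluded with a
logged reason. Z-scoring makes the epoch "mean change of activity" simply
the epoch mean, since the baseline mean is 0 by construction; a pre-anchor
re-baseline is available as a configurable alternative for late epochs.

Bleaching artifacts are screened by fitting `A·exp(−t/τ) + c` over the
baseline; a neuron is excluded when the fit explains ≥ 0.8 of the variance
*and* A ≥ 2 residual standard deviations. Both thresholds are configurable
and logged — the exclusion rule is stated qualitatively in the literature
("fits a defined exponential decay"), so explicit defaults are fixed here.

Slow baseline fluorescence is the output of a 2nd-order zero-phase
(forward–backward) Butterworth lowpass at 1/60 Hz; zero-phase filtering
squares the magnitude response, which the frequency-domain tests account
for. Dual-channel photometry is corrected by regressing the signal channel
on the isosbestic reference over the baseline window only (ordinary least
squares with intercept), predicting `F₀(t) = a·ref(t) + b` for the whole
session, and taking `ΔF/F₀ = (F − F₀)/F₀`; samples with non-positive
predicted F₀ are masked rather than silently inverted. Downsampling (8 Hz →
4 Hz for analysis; 1 Hz only for plotting, never for statistics) is plain
block averaging, which is anti-aliased by construction for the rate ratios
used.

### Classification and population summary

A neuron is *activated* in an epoch when its mean z change exceeds +1
(strict), *inhibited* below −1. The *exclusive* mode additionally requires
the epoch's mean to strictly exceed (activated) or fall strictly below
(inhibited) every other epoch's mean — the rule is stated in the literature
for the activated case; the mirrored condition for inhibition is this
package's symmetric completion. The population-weighted z-score is
`(n_class/n_total) × mean(z change over the class)`, zero for an empty
class.

### Onset latency and persistence

Onset (t50) is the midpoint of a 4-parameter logistic
`f(t) = floor + amp/(1 + e^−(t−t50)/s)` least-squares fitted to the
post-anchor rise. Because the response later decays, the fit is restricted
to the segment from the anchor to the peak of a 30-s moving average of the
trace; fitting the full window with a monotone logistic would bias the
midpoint. A multi-start grid (midpoints at the window quartiles × slopes
0.2/1/3 min) guards against local minima; non-convergent neurons are flagged
and excluded from latency statistics. Persistence — for which no standard
estimator exists; this is a declared reconstruction — is the duration the
smoothed trace stays above 50% of its peak change (the contiguous run
containing the peak), flagged as censored when the run touches the end of
the analysis window. Persistence is measured on the smoothed trace, not the
raw samples.

### Inference

Permutation tests use the difference in means (paired: mean of differences)
as the statistic — the statistic itself is not fixed by convention, and
alternatives are pluggable. Enumeration is exact when the number of distinct
relabellings (2ⁿ sign flips paired, C(n, n₁) reassignments unpaired) is
≤ 2²⁰; otherwise Monte Carlo with the add-one (Phipson–Smyth) convention
`p = (1+b)/(1+B)`, so p is never 0 and the test holds its size exactly for
continuous statistics. The intra-class correlation is the one-way
random-effects method-of-moments estimator: `ICC = σ²_between /
(σ²_between + σ²_within)` with the between-component clipped at zero when
the raw estimate is negative (reported unclipped in diagnostics).
Cross-condition correlations permute the neuron pairing (exhaustive up to
9! pairings) and report a t-based 95% confidence band for the fitted line.
Linear-mixed-model effect estimation is deliberately out of scope; the
response tables export cleanly for any external LMM fit.

### Cross-session matching

Neurons are matched across sessions by minimum-total-distance one-to-one
assignment of their centroids (Hungarian algorithm), restricted to pairs
within `max_dist` (default 15 μm, about one soma diameter). The
large-penalty construction makes the solution maximize the number of
within-radius matches first and minimize distance second. Footprint
correlation is not used; all matches are exported for manual verification,
which remains part of the procedure.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, with
defaults fixed to the study conditions: imaging at 8 Hz, photometry at
~1017 Hz (downsampled to 4 Hz for analysis), 10-min baseline, 1.2 ml
intragastric infusions at 100 μl/min (12 min), archetype mixture 22% oral /
39% systemic-activated (the reported water-session percentages) plus 10% GI
and 5% systemic-inhibited (plausible values; not reported for water
sessions), systemic onset mean 14 min after infusion start or 10.1 min after
drinking onset, persistence mean 30 min. Per-neuron spreads (1 min onset sd,
2 min persistence sd) are wider than the published standard errors — those
are errors of cohort means, not population spreads — and recovery tests
compare against per-neuron truth, so this choice does not loosen them.

Components:

* **Lick trains** — bouts with within-bout inter-lick intervals in
  [0.10, 0.20] s and inter-bout gaps strictly > 2 s, so the generator's own
  bout boundaries are exactly what bout detection must recover. Bouts
  shorter than 10 s are generated too and are, correctly, not ground-truth
  bouts.
* **Calcium transients** — a difference-of-exponentials kernel (0.2 s rise,
  1.5 s decay), resolvable at 8 Hz; kinetics are a free choice since sensor
  kinetics are preparation-dependent.
* **Systemic waveform** — the product of a rising and a falling logistic
  with midpoints at onset and onset + persistence, so the half-rise time and
  the above-half-peak duration equal the injected parameters by
  construction. The session's latent osmolality deviation has the same
  shape, scaled by infused volume and signed by tonicity (negative for
  water, positive for hypertonic saline); systemic responders' drive is an
  affine map of this latent, inhibited responders mirroring it.
* **Raw traces** — `offset + σ_noise·(white noise + amplitude·waveform)`,
  with amplitude ~ the peak z (default mean 4, "high SNR"); bleach neurons
  add a labelled decaying exponential. The baseline segment is stationary
  for non-bleach neurons.
* **Photometry** — signal = baseline·(1 + stage-weighted response) + shared
  artifact; reference = baseline′ + the same artifact at a different gain.
  The artifact is a smoothed low-frequency random walk; no published
  artifact model exists, and any shared additive process regression can
  cancel serves the purpose.
* **Training cohorts** — the ten-day protocol: two-bottle tests on days 1–2
  (bottle side randomized day 1, reversed day 2), six closed-loop training
  days (three per flavour, each lick triggering a 1 μl infusion of the
  mapped solution — water for one flavour, 600 mM NaCl for the other, in
  four counterbalanced groups), two-bottle tests on days 9–10. Preference
  for the water-paired flavour drifts by `daily_drift` per training day
  (clipped to [0,1]), giving a closed-form expected change of
  `6 × daily_drift`; training-day consumption scales linearly with current
  preference.

All draws come from SHA-256-keyed substreams of one seed, so outputs are
bit-identical under a fixed seed and adding neurons never changes existing
ones.

### What the generator does not emulate

Real recordings have correlated noise across neurons, slow non-exponential
drift, motion-correction residuals, neuropil contamination, and behavioural
idiosyncrasy (pauses, grooming, partial bouts) none of which are modelled.
Passing recovery tests therefore shows the estimators are correct for the
assumed signal model at the stated noise levels — not that the pipeline is
robust to every artifact of in-vivo data. The screening, masking and
diagnostic hooks exist precisely because real data will violate these
assumptions.

## Numerical choices

* Archetype counts use largest-remainder rounding, ties broken by archetype
  declaration order, so fractions map to counts deterministically.
* Strict inequalities at the ±1z boundary ("exceeded" means >).
* Otsu thresholding uses 256 equal-width bins over the filtered signal's
  range; a constant signal short-circuits to all-rest with a warning. When
  the histogram has an empty inter-mode gap the between-class variance ties
  across the gap; the first maximizing split is returned, and tests check
  attained optimality rather than a particular argmax.
* Curve fits (`curve_fit`) run with bounded parameters and multi-starts;
  bounds and starts are fixed in code, not data-dependent.
* Zero-phase filtering uses `sosfiltfilt` with its default reflect padding.

## Problem sizes in the test and acceptance runs

Recovery tests use 20 seeded sessions of 200 neurons at high SNR (the
reported cohort sizes are a few hundred neurons per condition); the
acceptance script uses 5 sessions per manipulation with rise fits on up to
40 neurons per session, 10 photometry sessions, 500 null replicates for
calibration, and a 12-mouse training cohort. These sizes give Monte-Carlo
error comfortably below the tolerances being checked.

## Known limitations

* Persistence estimation on smoothed traces is a reconstruction; other
  plausible estimators (fitting a rise×decay product directly) would give
  slightly different values near the tails.
* The exclusive classification mode's treatment of inhibition is a symmetric
  completion of a rule stated only for activation.
* `fit_rise` assumes a single monotone rise to a single plateau; multiphasic
  responses will fit poorly (flagged via R², not corrected).
* The speed-dependence of systemic onset on infusion rate is exposed only as
  a parameter hook; no functional form is shipped.
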