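# Methods

## Problem and model

A seizure-prediction model emits a binary alarm sample per time step; the
clinically limiting failure mode is the false alarm. `alarmcal` treats the
model as a black box and post-processes its output with a
threshold-parameterised transform

    g_lambda = max-pool_k ∘ majority-vote_{w, lambda}

where the causal majority vote sets sample *t* to 1 iff the fraction of
ones in the trailing window of `w` samples strictly exceeds `lambda`, and
max-pooling decimates the voted series into disjoint blocks of `k`
samples by block maximum. The vote suppresses pointwise noise; pooling
removes isolated mistakes and coarsens the decision rate. Raising
`lambda` can only turn alarms off (anti-monotonicity), so every
positive-count risk is non-increasing in `lambda`.

`lambda` is calibrated with the Learn Then Test recipe: for each
candidate `lambda` on a grid, per-unit empirical risks on an i.i.d.
calibration set are turned into a one-sided p-value for the null
hypothesis "the true mean risk at this `lambda` exceeds `alpha`", and a
familywise-error-rate (FWER) controlling multiple-testing procedure at
level `delta` converts the p-values into a validated set `Λ̂`. Every
member of `Λ̂` then satisfies P[R(λ) ≤ α] ≥ 1 − δ over the draw of the
calibration set — an (α, δ) risk-controlling prediction. We choose the
*minimum* validated `lambda` (the least restrictive threshold, hence the
best sensitivity); a caller-supplied hook can substitute any other
secondary-metric maximiser over `Λ̂`.

### p-values

`p = Φ((R̄ − α)·√n / s)` with the sample mean `R̄` and sample standard
deviation `s` (n − 1 divisor) of the per-unit risks — the central-limit
approximation, asymptotically valid, with no finite-sample guarantee. The
degenerate `s = 0` case is resolved as the limit of the z statistic:
`p = 0` if `R̄ ≤ α`, else `1`. Requires `n ≥ 2` units.

### Multiple-testing procedures

* **Bonferroni**: validate `{λ : p_λ ≤ δ/|Λ|}`; valid under arbitrary
  dependence, conservative.
* **Fixed-sequence testing (FST)**: test in the pre-declared order of
  *descending* `lambda` (strictest control first) at full level `δ`,
  stopping at the first failure. Valid here because the vote's
  anti-monotonicity makes p-values monotone along that order. FST
  validates a superset of Bonferroni's set under monotone p-values, so
  its chosen `lambda` is never larger.

An empty `Λ̂` is reported explicitly (`chosen_lambda = None`, a distinct
CLI exit status): the model cannot be calibrated to that `alpha`.

## Risk estimators

* `sample_fraction` (default, used throughout the synthetic study):
  false-positive samples divided by non-preictal samples, measured at the
  alarm output's own resolution; when pooling is on, labels are
  max-pooled with the same rate (a block is preictal if any of its
  samples is).
* `event_rate` (clocked records): false-alarm *events* (maximal runs of
  ones containing at least one non-preictal sample) per non-preictal
  hour. Clinically, an uninterrupted alarm is one alarm.

Pooling changes the resolution, so per-sample fractions of pooled and
non-pooled variants are not directly comparable; where the two variants
are compared, rates are first divided by the pooling rate to put them on
the per-input-step time axis.

## Synthetic data

The generator emulates the *structure* of seizure-prediction series, not
EEG itself: event points drawn i.i.d. Bernoulli(`p`) per sample are
spread forward over `w` samples (a point at *t* yields ones at
*t..t+w−1*, truncated at the series end), giving sparse windows of ones
when `p·w ≪ 1`; predictions are the ground truth flipped pointwise with
probability `p_flip` (a "noisy oracle"). Defaults `p = 0.005`,
`p_flip = 0.05`, `w = 8`, series length 1,000: a mostly-good but
imperfect predictor in the sparse regime (`p·w = 0.04`). One master seed
spawns an independent substream per series, so growing `n_series` never
reshuffles earlier series.

What the surrogate does *not* capture: temporally correlated model
errors, drift, class-dependent error rates, and the non-i.i.d. record
structure of real EEG splits — so passing the synthetic study
demonstrates the calibration machinery's guarantee under its stated
assumptions, not model quality on real data.

## The validation study

Each experiment draws a fresh dataset, splits it 50/50 by series into
calibration and test halves, calibrates at every requested `alpha` with
every multiple-testing method and pooling variant on the *same* data
(comparisons are paired within experiment), and scores the chosen
`lambda` on the held-out half. Cells report mean ± sd of the test
false-alarm fraction and accuracy (pointwise, at the output resolution,
against identically pooled labels), the modal chosen `lambda`, and the
count of empty-`Λ̂` experiments, which are excluded from means but never
dropped silently.

Full-scale protocol: 200 experiments × 10,000 series per `alpha` ∈
{0.001, 0.005, 0.01, 0.05, 0.1, 1}. The package's tests and the
reproduction script run a desk-scale version — 20 experiments × 2,000
series (and 200 × 200 for the coverage property) — chosen so the whole
suite completes in well under a minute while the binomial error bars on
the coverage checks (δ + 3·SE) remain meaningful.

## Numerical choices

* Strict `>` in both the vote and probability binarisation; the integer
  vote count is compared against the smallest count whose fraction
  exceeds `lambda`, evaluated with the same float semantics as the
  printed decimals, so `λ = 0.5` and `λ = 0.51` coincide for `w = 10`.
* Vote left edge zero-padded (pre-record time is alarm-free — the
  conservative choice for false alarms); pooling blocks are disjoint,
  the trailing partial block pooled as-is.
* Lambda grid default 0.51:0.99 step 0.01 — sub-majority thresholds are
  degenerate for a majority vote.
* Sensitivity is pooled over records (total TP over total seizures);
  reduction percentages are rounded to integers per record for
  reporting, and summary means average the per-record (rounded or
  externally supplied) reductions, unweighted or duration-weighted.

## EEG front end

EDF recordings (via `mne`) are band-passed to 0.5–75 Hz with a zero-phase
Hamming-window FIR filter (tap count targets a 0.4 Hz transition band,
capped so the forward–backward padding fits the record), then ten
descriptors are computed per channel over 6 s windows stepped by 3 s:
five relative band powers (delta 0.4–4, theta 4–8, alpha 8–13, beta
13–30, gamma 30–48 Hz; periodogram with a Hann taper, normalised by total
0.5–75 Hz power — note the delta band's lower edge sits below the filter
cut, kept as conventionally defined), spectral entropy (Shannon entropy
of the normalised spectrum, divided by log of the bin count, in [0, 1]),
the DFA scaling exponent (first-order detrending, log-spaced boxes from 4
samples to a quarter window), Hjorth mobility (first-difference ratio ×
sampling rate, ≈ 2πf for a sinusoid) and complexity (≈ 1 for a
sinusoid), and the Higuchi fractal dimension (k_max = 10). Zero-variance
windows yield all-zero features and a `degenerate` flag.

Preictal labels mark feature windows starting within [onset − 60 min,
onset − 30 s); the 30 s exclusion keeps the task prediction rather than
detection. Onsets before the record start are clipped with a warning.

## Known limitations

* The CLT p-value has no finite-sample guarantee; with few calibration
  units (e.g. a handful of records) the nominal (α, δ) contract can be
  violated. The coverage property is verified by simulation, not proof.
* Real-data record splits are typically not i.i.d.; the guarantee then
  holds only heuristically.
* `event_rate` risk counts an alarm spanning a preictal boundary as both
  a true positive and a false positive (conservative on both sides).
* Aggregating a pooled evaluation can merge two preictal windows that
  fall in adjacent blocks; record-level seizure counts are taken from the
  label resolution actually evaluated.
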