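# alarmcal

Risk-controlling calibration of binary alarm time series.

Seizure-prediction models (and alarm systems generally) are rarely usable
clinically because they fire too many false alarms, and improving the
model itself is the only lever most pipelines offer. `alarmcal`
decouples the two problems: it post-processes the binary output of *any*
black-box alarm model and calibrates the post-processing so the false
alarm rate is **statistically controlled at a user-chosen level**, at the
(explicit, measurable) cost of sensitivity. It is aimed at researchers
building EEG seizure-prediction systems and, more broadly, anyone who
needs distribution-free false-alarm control for a binary time series.

## The method

Model outputs pass through a threshold-parameterised transform
`g_λ = max-pool_k ∘ majority-vote_{w,λ}`: a causal window majority vote
(sample *t* fires iff the fraction of ones in the trailing `w` samples
strictly exceeds `λ`) followed by optional max-pooling into disjoint
blocks of `k` samples. Raising `λ` only ever removes alarms.

`λ` is calibrated with the **Learn Then Test** procedure. On a
calibration set of `n` independent units, the per-unit false-alarm risks
at each candidate `λ` yield a one-sided CLT p-value for the null
`R(λ) > α`:

    p_λ = Φ( (R̄(λ) − α) · √n / s(λ) )

and an FWER-controlling multiple-testing procedure at level `δ`
(Bonferroni, or fixed-sequence testing descending in `λ`) turns the
p-values into a validated set `Λ̂`. Every `λ ∈ Λ̂` satisfies

    P[ R(λ) ≤ α ] ≥ 1 − δ

over the draw of the calibration set — an (α, δ) risk-controlling
prediction. The chosen `λ̂` is the minimum of `Λ̂` (best sensitivity); an
empty `Λ̂` is an explicit "not controllable at this α" outcome, never an
error swallowed silently.

The package ships: the synthetic generator used to validate the guarantee
(sparse Bernoulli event windows + a noisy oracle), the calibrator, the
clinical metrics (event-based sensitivity, false alarms per non-preictal
hour, reduction percentages and their report arithmetic), an EEG front
end (EDF ingestion, 0.5–75 Hz FIR filtering, ten classical features over
6 s/3 s rolling windows, preictal labelling), a Monte Carlo study runner,
and an `alarmcal` CLI (`generate` / `calibrate` / `evaluate` / `study` /
`features`). See `docs/methods.md` for the full model description.

## Worked example

```python
import numpy as np
from alarmcal import (SyntheticParams, generate_dataset, CalibrationConfig,
                      PostprocessParams, calibrate)

params = SyntheticParams(event_rate=0.005, label_window_len=8,
                         flip_prob=0.05, series_len=1000, n_series=400, seed=42)
labels, preds = generate_dataset(params)

config = CalibrationConfig(
    alpha=0.01, delta=0.1, mhc_method="fixed_sequence",
    postprocess=PostprocessParams(vote_window_len=10, pool_size=10,
                                  pooling_enabled=True),
)
result = calibrate(labels[:200], preds[:200], config)
print("chosen lambda:", result.chosen_lambda)
print("calibration mean risk at chosen lambda:",
      round(result.mean_risks[result.chosen_lambda], 5))

from alarmcal.calibration import unit_risk_matrix
test_risks = unit_risk_matrix(labels[200:], preds[200:], config.postprocess,
                              [result.chosen_lambda])
print("held-out mean false-alarm fraction:", round(float(test_risks.mean()), 5))
```

prints

```
chosen lambda: 0.7
calibration mean risk at chosen lambda: 0.00708
held-out mean false-alarm fraction: 0.00731
```

Read: of the grid 0.51…0.99, fixed-sequence testing validated every
threshold from 0.70 up; the least restrictive validated vote threshold is
0.70, its mean per-sample false-alarm fraction is 0.007 on the
calibration half and 0.007 on the held-out half — both below the
requested α = 0.01, as the (α, δ) contract promises with probability
≥ 0.9.

The same flow from the shell:

```sh
alarmcal generate --seed 42 --n-series 400 --out ds
alarmcal calibrate --labels ds_labels.csv --predictions ds_predictions.csv \
    --alpha 0.01 --out calibration.json
alarmcal study --scale 0.1 --seed 7 --out study_out/
```

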