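# chrononet

Early-warning prediction of acute kidney injury (AKI) from hourly clinical
time series.

AKI is usually recognized late: serum creatinine and urine output — the
variables that define it — respond hours after renal function has already
deteriorated. This package implements an LSTM-based risk model with
temporal attention that emits an AKI risk probability at every hour of a
patient's record, together with everything needed to build and test such a
model without access to restricted clinical data: a KDIGO rule engine for
labeling, a synthetic ICU cohort generator with a planted pre-onset signal,
class-imbalance machinery (SMOTE + cost-sensitive/focal losses), multi-task
heads for recovery and dialysis outcomes, and inference-time dynamic
evaluation with an elastic anchor. It is aimed at methods researchers in
clinical ML who need a fully inspectable, deterministic reference pipeline.

## Model

For patient *i* with inputs `x_i(t) ∈ R^d`, `t = 1..T` (6 ≤ T ≤ 48 hourly
steps), an LSTM encoder produces hidden states `h_t`; per-step risk is

    ŷ_i(t) = σ(W_o h_t + β_o)

trained with masked sequence binary cross-entropy plus an L2 penalty
`λ‖θ‖²` and a temporal-smoothness penalty `γ Σ_t (ŷ(t) − ŷ(t−1))²`.
In pooled mode, temporal attention

    e_t = vᵀ tanh(W_h h_t + b_h),   α = softmax(e),   c = Σ_t α_t h_t

summarizes the sequence as a convex combination of hidden states
(optionally with a patient-adaptive query `v = W_z z + b_z` from the static
profile), with an entropy regularizer on α. Labels follow the KDIGO
criteria: creatinine rise ≥ 0.3 mg/dL within 48 h, creatinine ≥ 1.5× the
7-day rolling-minimum baseline, or urine output < 0.5 mL/kg/h for more than
6 consecutive hours. Three sigmoid heads on the shared representation
predict AKI, recovery and dialysis, combined with fixed or
uncertainty-based task weighting. Full details and all numerical
conventions are in [docs/methods.md](docs/methods.md).

The network and losses run on a small built-in reverse-mode autodiff
engine (float64), so analytic gradients are exact and checked against
finite differences in the test suite.

## Worked example

```python
import numpy as np
from chrononet import (SimConfig, simulate_cohort, apply_cohort_filters,
                       ChronoNetParams, ModelConfig, TrainConfig,
                       LossConfig, train)

cohort = simulate_cohort(SimConfig(n_patients=1000, signal_effect=1.0,
                                   seed=7))
cohort, report = apply_cohort_filters(cohort)
print(report["n_retained"],
      np.mean([p.outcome_aki for p in cohort.profiles]))
# 1000 0.307

params = ChronoNetParams(ModelConfig(d=cohort.d, d_h=32, d_a=16, seed=3))
params, logs = train(cohort, params,
                     TrainConfig(lr0=0.1, epochs=15, d_h=32, d_a=16,
                                 seed=3),
                     LossConfig(l2_lambda=1e-5, smooth_gamma=0.1,
                                class_weights=(0.7, 1.6)))
print(max(l["val_auc"] for l in logs))
# 0.9347319347319347
```

The cohort carries a planted creatinine drift beginning 12 h before each
AKI onset; the trained model separates oncoming AKI from stable patients
with validation AUROC ≈ 0.93 — i.e. the pipeline recovers the temporal
signal the generator is known to contain. The same pipeline is scriptable
from the shell:

```sh
chrononet simulate --seed 1 --out data/
chrononet label --data data/ --out labels/
chrononet resample --data data/ --config resample.yaml --seed 1 --out balanced/
chrononet train --data data/ --config train.yaml --seed 1 --out run/
chrononet evaluate --data data/ --checkpoint run/checkpoint.npz --out metrics.json
```

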