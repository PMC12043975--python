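# mmforecast

Probabilistic blood-work forecasting and progression-event prediction for
multiple myeloma (MM).

MM patients on treatment are followed every ~3 months with a routine blood
panel — hemoglobin, calcium, creatinine, LDH, albumin, β2-microglobulin,
M-protein, free light chains κ/λ, and white cells. These trajectories carry
the early signature of relapse, but standard risk scores use only baseline
values. `mmforecast` is for researchers who want to exploit the longitudinal
signal: it learns a generative model of future blood work from past visits,
flags forecasted visits that meet a progressive-disease (PD) condition, and
quantifies how far ahead such events can be anticipated.

## The models

**Forecaster** — an LSTM encoder (10 inputs, 32 memory cells) summarizes a
patient's history into a state c; three affine networks condition a
Gaussian–Bernoulli restricted Boltzmann machine on c via a visible bias
b(c) ∈ ℝ¹⁰, a diagonal precision d(c) = softplus(·) > 0 and a coupling
matrix W(c) ∈ ℝ¹⁶ˣ¹⁰ (no hidden bias). With z = √d ⊙ (v − b),

    E(v, h) = ½‖z‖² − hᵀ W z ,
    p(h_j = 1 | v) = σ((Wz)_j),   v_i | h ~ N(b_i + (Wᵀh)_i/√d_i, 1/d_i).

Forecasts are Monte-Carlo: 1,000 chains × 32 block-Gibbs steps per visit,
sampled visits fed back into the encoder recurrently; the point forecast is
the ensemble mean and the 95% sleeves its empirical percentiles. Training is
contrastive divergence with AdamW (lr 1e-4, 100 epochs, batch 32,
per-component weight decay). Trainable total: 11,572 parameters.

**Annotator** — an LSTM (6 inputs, 8 cells) plus a 2-way softmax head
(530 parameters) scores each visit's PD probability from the prefix up to
that visit, using M-protein, both free light chains, their ratio and both
signed differences. The rare PD class is upsampled to parity during
training; the decision threshold maximizes F_β (β = 5, recall-weighted) on
training data only.

**Metamodel** — forecast m visits ahead, invert to raw units, annotate the
forecasted visits: progression probabilities before the blood is drawn.

Everything runs on a synthetic cohort generator that emulates the study
conditions (3-monthly visits, cross-correlated analytes with momentum,
induction response, stochastic relapse with marker regrowth, ~7% per-visit
PD prevalence, missingness), so no gated clinical data are needed. See
`docs/methods.md` for the full model and design documentation.

## Worked example

Simulate a small labeled cohort and run a 2-fold study (≈1 minute on one
CPU core):

```sh
mmforecast simulate --seed 3 --out cohort.csv --config demo.yaml
mmforecast evaluate --cohort cohort.csv --config demo.yaml --seed 3 \
    --out report/ --save-checkpoints ckpts/
```

with `demo.yaml`:

```yaml
n_patients: 80
n_visits: 16
k: 2
relapse_hazard: 0.06
eval_trajectories: 100
```

`report/report.json` then contains the fold-aggregated tables; the run
above prints (abridged):

```
"pooled_mse": {"1": {"model": {"mean": 0.105, ...},
                     "LOCF":  {"mean": 0.110, ...},
                     "MA":    {"mean": 0.178, ...}}},
"annotation": {"auroc": {"mean": 0.780, "sd": 0.048, "n_folds": 2}},
"metamodel":  {"1": {"auroc": {"mean": 0.663, ...}},
               "5": {"auroc": {"mean": 0.590, ...}}}
```

read as: the trained forecaster's pooled one-step mean squared error
(0.105, transformed scale) undercuts carrying the last observation forward
(0.110) and a 3-visit moving average (0.178); the annotator separates PD
from non-PD visits on held-out patients with AUROC 0.78; and the composed
metamodel anticipates progression events one visit ahead with AUROC 0.66,
decaying toward chance five visits (15 months) out. At the package's
default study scale — 200 patients × 20 visits, 5 folds — the same pipeline
reaches held-out annotation AUROC ≈ 0.87 and metamodel AUROC ≈ 0.86 at 3
months declining to ≈ 0.74 at 15 months (recomputed by
`scripts/acceptance.py`, below).

Forecast a single patient with uncertainty sleeves:

```sh
mmforecast forecast --cohort cohort.csv --checkpoint ckpts/fold1.ckpt \
    --patient SYN_00 --prefix 7 --horizon 5
```

which emits per-visit point forecasts with 95% bands in raw units (g/dL,
mg/L, …) for all ten analytes.

A full-scale run (`mmforecast all --seed 1 --out study/`) uses the default
200-patient × 20-visit cohort, 5 folds and the full-scale hyperparameters,
and takes on the order of ten minutes on one CPU core.

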