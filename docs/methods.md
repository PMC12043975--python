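# Methods

This note documents the models, the synthetic study design, the numerical
choices, and the limitations of `mmforecast`.

## Problem setting

Multiple myeloma (MM) patients on treatment are followed roughly every three
months with a routine blood panel. Ten analytes carry most of the
disease-monitoring signal: hemoglobin (Hb), calcium (Ca), creatinine (Cr),
lactate dehydrogenase (LDH), albumin (Alb), beta-2-microglobulin (β2m),
M-protein (M-Pr), the serum free light chains κ and λ (SFL-κ, SFL-λ), and
white blood cells (WBC). The package forecasts these trajectories and flags
visits at which the consensus-style relapse condition — progressive disease
(PD) — is met, before the visit happens.

## Forecasting model

The forecaster is a hybrid of a recurrent encoder and a conditional
Gaussian–Bernoulli restricted Boltzmann machine (CRBM).

**Encoder.** A single-layer LSTM with 10 inputs and 32 memory cells consumes
the (power-transformed) visit sequence and summarizes it in its final hidden
state c ∈ ℝ³². The dual-bias convention is used, so the layer holds
4·H·(I+H+2) trainable scalars.

**Conditional RBM.** Three affine networks map c to the RBM over the next
visit v ∈ ℝ¹⁰ with 16 binary hidden units h:

* bias network: b(c) ∈ ℝ¹⁰,
* precision network: d(c) = softplus(affine(c)) ∈ ℝ¹⁰, strictly positive,
* weights network: W(c) ∈ ℝ¹⁶ˣ¹⁰ (a 160-dimensional affine output, reshaped).

There is no hidden bias. In whitened coordinates z = √d ⊙ (v − b) the energy
is

    E(v, h) = ½‖z‖² − hᵀ W z,

giving the exact block conditionals p(h_j = 1 | v) = σ((Wz)_j) and
v_i | h ~ N(b_i + (Wᵀh)_i/√d_i, 1/d_i). The trainable total is exactly
4·32·(10+32+2) + 2·(32·10+10) + (32·160+160) = 11,572 scalars. The
annotation model (below) totals 4·8·(6+8+2) + (8·2+2) = 530.

**Sampling.** A single-step prediction draws 1,000 independent chains of 32
block-Gibbs alternations, each initialized at the conditional-mean start
v = b(c). Multi-step forecasts run each chain recurrently: sample the next
visit, feed the *sampled* visit back into the encoder, re-condition, and
repeat to the horizon — so the ensemble is a set of complete trajectories,
not isolated marginals. The point forecast is the entrywise ensemble mean
("most probable trajectory"); 95% sleeves are the empirical 2.5/97.5
percentiles. Evaluation sweeps use a 200-chain ensemble: the Monte-Carlo
standard error of the point forecast scales as σ/√n and is already an order
of magnitude below the residual noise floor at n = 200; single-patient
forecasts keep the 1,000-chain default.

**Training.** Contrastive divergence (CD-1 by default, configurable up to
the sampler's step count): for each (prefix, next-visit) instance the loss
gradient is ∇F(v⁺) − ∇F(v⁻), where F is the free energy, v⁺ the observed
next visit and v⁻ a k-step Gibbs reconstruction started from v⁺ with
gradients blocked through the sampled values. Optimization uses AdamW
(lr 1e-4, 100 epochs, batch 32) with decoupled weight decay per component:
encoder 0.1, bias net 0.1, precision net 0.1, weights net 0.2. All gradient
paths (through the three nets, softplus, and backpropagation through time in
the masked LSTM) are exact and finite-difference-checked in the test suite.
The recorded loss trace is the per-epoch mean reconstruction error, the
standard monitored quantity for CD training; the CD free-energy gap itself
is optimized but not a proper loss.

**Initialization.** Training starts at the trivial carry-forward baseline:
the first ten memory cells are wired to pass the most recent visit through
their gates (input/output gates saturated open, forget gate closed, a small
0.1 squash keeping tanh near-linear), the bias network reads them back at
the least-squares gain of that scalar response under a standard-normal input
weighting, couplings start near zero and precisions at one. Before any
training the forecaster is therefore approximately "LOCF plus unit Gaussian
noise", and CD refines from a sensible operating point instead of having to
rediscover the carried-forward level at a small learning rate. Batches of
variable-length prefixes are left-padded with a mask; masked steps leave the
recurrent state and gradients untouched.

## Annotation model

A per-visit PD-probability model on six myeloma-specific inputs derived on
the raw scale: M-Pr, SFL-κ, SFL-λ, the ratio κ/λ, and both signed
differences κ−λ and λ−κ. Each derived column gets its own fold-fitted power
transform. An LSTM (6 inputs, 8 memory cells) reads the prefix up to and
including the current visit; a dense 2-way softmax head on its final state
yields p(PD). Training instances are (prefix ending at t, label at t) pairs;
the rare PD class is upsampled with replacement to exact parity (feature
values are never altered); the loss is cross-entropy, AdamW lr 1e-4,
200 epochs, batch 128, weight decay 1 on both components. Evaluation always
runs on the natural, unbalanced data.

**Threshold calibration.** The decision threshold maximizes
F_β = (1+β²)·precision·recall / (β²·precision + recall) with β = 5,
weighting recall five-fold — missing a progression is clinically costlier
than a false alarm. The scan is exhaustive over all distinct scores plus
{0, 1}; ties break toward the lower threshold (higher recall). Calibration
uses training data only.

## Metamodel

The progression-forecasting metamodel chains the two parts: forecast the
next m visits (point forecast on the transformed scale), invert to raw
units, append to the observed prefix, derive the annotation features on the
concatenation, and score the forecasted positions. The annotator sees the
mean point-forecast trajectory, matching its "most probable trajectory"
role; scoring each sampled trajectory instead is available as an option.

## Synthetic cohort generator

The generator defines the study conditions; nothing downstream ever sees
real patient data. Per patient:

* **Baseline levels** are drawn from a 10-variate normal with physiologic
  means/SDs and a correlation structure encoding the clinically expected
  signs (Cr–β2m +0.6, SFL–Alb −0.3, SFL–Cr +0.25, Hb–β2m −0.25, κ–λ −0.2,
  …), clipped to positive floors. The involved light chain (the larger
  baseline draw) is amplified 3× for clonal excess.
* **Induction response**: M-Pr and the involved SFL ramp linearly over the
  first 4 visits to a 20% residual-disease floor.
* **Momentum**: every analyte follows a mean-reverting AR(1) around its
  (time-varying) target with per-feature coefficient 0.7 and innovation SDs
  at routine-lab magnitudes (M-Pr 0.10 g/dL, SFL 4 mg/L, Hb 0.45 g/dL, …).
* **Relapse**: from visit 7 (a realistic first-line remission duration) a
  2%/visit hazard starts multiplicative regrowth of M-Pr and the involved
  SFL at 30%/visit, with downstream coupling — Cr and β2m targets rise,
  Alb and Hb fall — scaled by the relative marker excess.
* **Labels**: a visit is PD when M-Pr ≥ 1.25× its running nadir with an
  absolute rise ≥ 0.5 g/dL, or the involved-minus-uninvolved SFL difference
  ≥ 1.25× its nadir with a rise ≥ 100 mg/L. The rule is deterministic,
  prefix-causal and idempotent; it is a ground-truth generator in the shape
  of the consensus relapse convention, not a claim of clinical equivalence.
  Under the defaults this yields a per-visit PD prevalence of ~7–8%
  (5.8–10.1% across seeds), matching the low-prevalence regime the models
  target.
* **Missingness**: independent per-cell (MCAR) with per-feature rates
  echoing the sparsity ordering of real registries (β2m 0.30, LDH 0.25,
  M-Pr/SFL 0.10, others 0.05) at trial-like magnitudes; the first visit of
  the three disease markers always stays observed so labels remain
  computable. Hidden values are retained under the mask for oracle use.

What the generator does **not** emulate: irregular visit spacing, treatment
arms and their pharmacodynamics, informative (MNAR) missingness,
cytogenetic risk strata, survival endpoints, measurement-platform shifts.
Passing the desk benchmark therefore demonstrates that the pipeline learns
and evaluates correctly under the assumed statistical structure — not
clinical performance on real cohorts.

## Preprocessing

Patients with any analyte never measured across all visits are excluded;
remaining gaps are imputed by last-observation-carried-forward with leading
backfill from the earliest observation, never crossing patients; backfilled
cells are flagged so evaluations could exclude them. Each analyte is then
Yeo–Johnson power-transformed (maximum-likelihood exponent via
scikit-learn's transformer) and standardized to mean 0/SD 1 — with all
parameters fitted on the training portion of each fold only. The inverse
transform saturates just inside the transform's range boundary (bounded
above for λ < 0, below for λ > 2) so that extreme forecasts invert to
finite raw values. Patient-level 5-fold splits are seeded shuffles into
near-equal test sets.

## Evaluation suite

* **Forecast accuracy**: squared error on the transformed scale per feature
  × horizon (1–5 visits ≙ 3–15 months), for the model and the LOCF and
  3-visit moving-average baselines (the MA window shrinks to the prefix
  length when the prefix is shorter); fold-level MSEs are compared by a
  one-sided Mann-Whitney U test (exact null when both samples ≤ 8 and
  tie-free, midrank normal approximation with tie correction otherwise).
  An "extreme change" subset restricts to cells whose actual change from
  the previous visit exceeds one training-split SD of such changes
  (≈31.7% of cells under Gaussian innovations).
* **Statistical fidelity**: Pearson r between forecast and actual per
  feature/horizon; r between Δ_model and Δ_true (changes from the last
  known value — identically zero for LOCF, hence baselines are excluded);
  cross-correlation and lag-correlation matrices of forecasted vs actual
  data compared by least-squares regression (slope, intercept, R²).
  Undefined correlations (constant series) propagate as missing, not zero.
* **Discrimination**: AUROC (midranks for ties), AUPRC (average precision,
  chance level = prevalence), sensitivity/specificity at the fold's
  training-calibrated threshold; prior-observation × horizon grids with
  fold-mean cells, single-class cells reported missing. Per-horizon
  summaries pool the grid's prior lengths (2, 4, 6, 8, 10, 12 visits).
* **Clinical utility**: PPV = sens·prev / (sens·prev + (1−spec)(1−prev))
  and the flagged fraction (that same denominator).
* **External validation**: every fold's frozen transforms, models and
  threshold are applied to one full external cohort; per-fold metrics and
  mean ± SD are reported; nothing is refitted.

## Determinism and problem sizes

A single run seed expands into per-component streams via
`SeedSequence([seed, component_id])` with a fixed component registry, and
per-fold integer seeds via `(seed·31 + fold) mod (2³¹−1)`. Identical seeds
reproduce cohorts, trained weights, forecasts and reports bit-for-bit.
Checkpoints are stored-ZIP archives (fixed timestamps) holding a JSON
manifest and concatenated little-endian float64 tensor bytes;
save → load → save is byte-identical.

The documented desk scale — 200 patients × 20 visits, 5 folds, 200-chain
evaluation ensembles — was chosen so a full study runs in minutes on one
CPU core while keeping every qualitative property of the full-size design
(low prevalence, fold-wise variability, horizon degradation).

## Known limitations

* CD-1 estimates the likelihood gradient with a one-step reconstruction;
  the learned conditional distribution is sharper near the data manifold
  than a full maximum-likelihood fit would be.
* The carry-forward initialization biases early training toward
  persistence; on data without momentum the encoder must partially unlearn
  it (the stationary-recovery test shows it does).
* The point forecast averages transformed-scale samples before inversion;
  on the raw scale this is the inverse-transformed mean, not the mean of
  inverse-transformed samples.
* Correlation summaries pool observations across patients; per-patient
  correlation averaging would weight patients equally instead.
* The lag-correlation comparison uses a common forecast segment (prefix 7,
  five steps) and omits patients with shorter records.
* The annotator generalizes worst to patients whose progression presents at
  low absolute marker burden (small secretory clones): with only absolute
  marker features per visit, the network favors level-based shortcuts over
  rise-from-nadir dynamics, and fold-level held-out AUROC varies accordingly
  even when training discrimination is near-perfect.
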