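# abxcease

Individualised **antibiotic-cessation outcome estimation** for ICU patients:
for every day of a patient's antibiotic course, estimate what their length of
stay (LOS) and mortality would be under the two alternative actions — *stop
antibiotics today* vs. *continue* — from routinely collected EHR-like daily
data.

The package is aimed at methods researchers in clinical machine learning and
causal inference who want a fully testable, self-contained implementation of
this estimator: because the question is counterfactual ("what would have
happened had we stopped earlier?"), it ships a synthetic ICU-cohort simulator
with a *known* causal effect of cessation timing, so every stage — and the
final effect estimate — can be scored against ground truth.

## Method

1. **Per-day patient embeddings.** A bi-directional LSTM sequence autoencoder
   (NumPy, exact backpropagation through time) reads the daily feature matrix
   x⟨1⟩…x⟨T⟩ of a stay (values, missing-value indicators, treatment
   covariates) and is trained with a combined loss

   L = w_r · L_r + w_s · L_s,

   where L_r is the RMSE of the reversed-order reconstruction over observed
   cells and L_s is a supervised loss from a linear head on the embedding z
   (RMSE against the LOS label, binary cross-entropy against mortality). L_s
   makes the embedding space a good linear predictor of the outcome. The
   embedding of day t uses days 1..t only. Two task-specific models are
   trained (LOS, mortality), each keeping its best-validation epoch
   (RMSE / AUROC) over the training run.

2. **Synthetic-control counterfactuals.** For each day t the embeddings of
   all stays are partitioned into a *continue* pool (on antibiotics on day t)
   and a *stop* pool (first antibiotic-free day is t). For a subject-day, the
   k = 10 nearest donors (Euclidean distance) are drawn from each pool and
   ridge weights solve

   Loss_i = Σ_d [ z_{i,d} − Σ_j x_{j,d} w_{i,j} ]² + λ Σ_j w_{i,j}²,   λ = 1,

   in closed form; the stop and continue outcomes Ỹ_i^{S,t}, Ỹ_i^{C,t} are
   the (normalised) weighted averages of donor outcome labels. A subject is
   never its own donor.

3. **Control/impact evaluation.** Each treated day is a *stop-impact* /
   *continue-control* day; the in-ICU cessation day is *stop-control* /
   *continue-impact*. On control days the factual outcome is known, so
   μΔ = mean_i [ mean_t ( Y_i − Ỹ_i^t ) ] measures calibration; on impact
   days it estimates the effect of the unobserved action. Significance uses
   the two-sided Wilcoxon rank-sum test (α = 0.05); LOS error is reported as
   MAPE/MAE (stay-first averaging) and pooled RMSE; mortality estimates get
   the AUROC/AUPRC/accuracy/precision/recall/specificity/F1 family with
   percentile-bootstrap CIs.

## Worked example

```python
from abxcease import SimConfig
from abxcease.experiments import recovery_experiment

# 2,000-stay synthetic cohort in which each avoided antibiotic day truly
# shortens LOS by 0.8 days; train the LOS encoder and estimate stop/continue
# outcomes for every antibiotic day of every stay.
res = recovery_experiment(0.8, n_stays=2000, seed=1, epochs=20)
print(f"stop-control  mean delta  {res.stop_control_mu:+.3f} d")
print(f"continue-control mean delta {res.continue_control_mu:+.3f} d")
print(f"stop-impact   mean delta  {res.stop_impact_mu:+.3f} d  (p={res.stop_impact_p:.1e})")
print(f"true mean effect          {res.true_mean_effect:+.3f} d")
print(f"relative error            {res.relative_error:.1%}")
```

prints (seed 1):

```
stop-control  mean delta  +0.127 d
continue-control mean delta -0.388 d
stop-impact   mean delta  +1.323 d  (p=3.7e-217)
true mean effect          +1.718 d
relative error            23.0%
```

Control-day deltas near zero (≲ 9% of the cohort LOS SD of 4.3 d) say the
estimator reproduces known outcomes where they are observable; the positive,
significant stop-impact delta recovers the simulator's true mean cessation
effect to within a quarter. With the effect set to 0 the stop-impact test is
non-significant in ~9 of 10 replicate cohorts.

The same pipeline is scriptable end to end:

```bash
abxcease run-all --seed 7 --out runs/demo          # simulate → … → evaluate
abxcease run-all --seed 7 --out runs/demo-ablation --ablation
```

which writes the cohort tables, processed timelines, two model checkpoints,
the per-day stop/continue estimate table, the evaluation report and a
content-hash manifest. Real (e.g. credentialed EHR) data can replace the
simulator by supplying the same three CSV tables at the preprocess boundary.

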