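# lpdstrat

Latent process decomposition (LPD) and DESNT-based stratification of
prostate-cancer expression cohorts.

## The problem

Bulk prostatectomy expression profiles are mixtures: a single sample can
contain several cancer lineages plus benign tissue, so hard clustering
(hierarchical, k-means, …) assigns each patient to one group and discards
the heterogeneity that carries prognosis. LPD is a mixed-membership model —
the expression profile of sample *a* is decomposed over K latent
*signatures*, each a full per-gene Gaussian pattern:

    θ_a ~ Dirichlet(α),   z_ga | θ_a ~ Cat(θ_a),
    e_ga | z_ga = k ~ N(μ_gk, σ²_gk)

The per-sample weight θ̂ of the poor-prognosis **DESNT** signature is then
a *continuous* prognostic variable for biochemical (PSA) recurrence after
prostatectomy: it enters Cox proportional-hazards models alongside Gleason
grade, PSA, stage and margin status, is cut into four bands (< 0.001,
0.001–0.3, 0.3–0.6, ≥ 0.6) for Kaplan–Meier display, and feeds a
points-based nomogram predicting recurrence-free survival at 1/3/5/7 years.

The package provides, for bioinformaticians and biostatisticians working
with bulk expression + clinical endpoints:

- `LatentProcessDecomposition` — variational-EM fitting (uniform or
  estimated Dirichlet prior), restart ensembles, hold-out-likelihood
  selection of K, model serialisation;
- **OAS projection** (`project_sample` / `project_dataset`) — decompose new
  samples against a frozen model in milliseconds, one sample at a time, the
  operation that makes clinical deployment practical;
- `stratify` — argmax signature assignment, DESNT proportion + banding,
  representative-run selection, signature labelling, cross-dataset profile
  correlations, χ² over-representation, pathway activation scores,
  differential expression with cross-run consensus;
- `survival` — KM/log-rank, Cox PH (Breslow ties) with DESNT as a
  continuous covariate, Harrell's C with optimism bootstrap, calibration,
  and nomogram construction;
- `simulate` — a generative synthetic-cohort module with full ground truth
  (expression, survival with a planted log hazard ratio, binary genomic
  labels), which is how the whole pipeline is tested.

See `docs/methods.md` for the model, the numerical choices and the
generator's scope.

## Worked example

Fit a four-signature decomposition of a synthetic 150-sample × 300-gene
cohort and regress recurrence on the risk-signature proportion:

```python
import numpy as np
from lpdstrat import simulate, LatentProcessDecomposition, match_signatures
from lpdstrat import stratify as st, survival as sv

cohort = simulate.simulate_cohort(simulate.SimulationConfig(seed=7))
res = LatentProcessDecomposition(cohort.expression, 4, prior="estimated").fit(seed=0)
print(res.summary())
```

```
Latent Process Decomposition Results
====================================================
Signatures (K):        4
Genes:                 300
Samples:               150
Prior mode:            estimated
Converged:             True (322 iterations)
Final bound:           -63675.8530
alpha:                 0.0634 0.0674 0.0539 0.0598
```

The small estimated α (≈ 0.06 per signature) says membership is sparse:
most samples are dominated by one signature. Identify the planted risk
signature, band the cohort, and fit the Cox model:

```python
perm = match_signatures(res.model.mu, cohort.truth.mu)
risk = int(np.where(perm == cohort.truth.risk_signature)[0][0])
table = st.stratification_table(res.decomposition, risk)
print(table["desnt_band"].value_counts().sort_index())

df = cohort.clinical.assign(desnt=res.theta[:, risk])
print(sv.fit_cox(df, ["desnt", "gleason", "psa", "stage", "margins"]).summary())
```

```
desnt_band
1    86
2    24
3     7
4    33

Cox proportional hazards (Breslow ties)
================================================================
n = 150, events = 120, training C-index = 0.558

covariate              coef      HR            95% CI           p
desnt                 0.568   1.765  [1.05, 2.96]    3.09e-02
gleason[3+4]          0.094   1.098  [0.68, 1.76]    6.98e-01
gleason[4+3]         -0.012   0.989  [0.57, 1.72]    9.68e-01
gleason[gt7]          0.012   1.013  [0.57, 1.79]    9.66e-01
psa                   0.019   1.019  [0.98, 1.05]    2.80e-01
stage[T3-T4]          0.143   1.154  [0.76, 1.74]    4.96e-01
margins               0.234   1.263  [0.81, 1.96]    3.00e-01
```

Half the cohort carries essentially no DESNT (band 1); the DESNT
proportion is the only significant covariate (HR 1.77 per unit proportion,
p = 0.03 at this small n; the generator plants HR = 2 and draws the
clinical covariates independently of the signatures, so their HRs hover
around 1). `sv.build_nomogram(cox, ranges)` re-parameterises the fitted
model into 0–100 point scales, and `res.project(X_new)` classifies new
samples without refitting.

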