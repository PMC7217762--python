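# Methods

## The model

`lpdstrat` implements latent process decomposition (LPD), a mixed-membership
model for bulk expression cohorts. For sample *a* with expression value
*e<sub>ga</sub>* at gene *g*:

- θ<sub>a</sub> ~ Dirichlet(α) — per-sample weights over K latent
  *signatures*;
- z<sub>ga</sub> | θ<sub>a</sub> ~ Categorical(θ<sub>a</sub>) — each gene in
  each sample is generated by one signature;
- e<sub>ga</sub> | z<sub>ga</sub> = k ~ N(μ<sub>gk</sub>, σ²<sub>gk</sub>).

Unlike hard clustering, a sample is a *mixture* of signatures. This is the
right abstraction for prostatectomy specimens, which routinely contain
several cancer lineages plus benign tissue: the biologically meaningful
quantity is the per-sample *proportion* of a poor-prognosis signature
(DESNT), not a single cluster label. Downstream, that proportion enters a
Cox proportional-hazards model of biochemical recurrence as a continuous
covariate, is cut into four prognostic bands (< 0.001, 0.001–0.3, 0.3–0.6,
≥ 0.6), and is combined with Gleason grade, PSA, pathological stage and
surgical-margin status in a points-based nomogram.

### Inference

Mean-field variational EM with q(θ<sub>a</sub>) = Dirichlet(γ<sub>a</sub>)
and q(z<sub>ga</sub>) = Q<sub>·ga</sub>:

- E-step: Q<sub>kga</sub> ∝ N(e<sub>ga</sub>; μ<sub>gk</sub>, σ²<sub>gk</sub>)
  · exp ψ(γ<sub>ak</sub>), normalised over k; γ<sub>ak</sub> = α<sub>k</sub> +
  Σ<sub>g</sub> Q<sub>kga</sub>. The additive identity Σ<sub>k</sub>
  γ<sub>ak</sub> = Σ<sub>k</sub> α<sub>k</sub> + G holds after every E-step
  and is asserted in tests.
- M-step: responsibility-weighted Gaussian mean/variance per (gene,
  signature), variance floored at 1e-6.
- α: "uniform" mode holds α = (1, …, 1) fixed (the maximum-likelihood
  variant); "estimated" mode maximises the bound's Dirichlet term by damped
  Newton with Minka's O(K) Hessian inversion.

Every update is coordinate ascent on one evidence lower bound, so the bound
is non-decreasing; the fitting loop raises if it ever decreases by more than
1e-8 relative. Convergence is a relative bound change below 1e-6 (at most
2000 iterations). Per-sample proportions are reported as
θ̂<sub>ak</sub> = γ<sub>ak</sub>/Σ<sub>k'</sub>γ<sub>ak'</sub>.

Two numerical choices matter and are deliberate:

1. **Initialisation.** γ is initialised at α + G/K plus Uniform(0, 0.1·G/K)
   noise; initial signature means are the gene means plus 0.1 gene-sd
   Gaussian jitter. Without the mean jitter, EM can linger at (and, under a
   loose tolerance, terminate in) the exchangeable-signature saddle where
   all signatures stay identical.
2. **Two-stage α estimation.** In "estimated" mode, α stays at 1 until the
   bound first converges, then α updates switch on and fitting continues to
   a second convergence. Estimating α from the first iteration lets α
   collapse before the Gaussian parameters have separated, which locks in
   markedly worse local optima. Both stages ascend the same bound, so the
   monotonicity guarantee is unchanged.

Degenerate signatures (posterior mass below 1e-3·G) are re-seeded from the
worst-fitting sample; this restarts the bound-monotonicity baseline and is
logged. It does not trigger under the default study conditions.

### Restarts and the representative run

EM is multi-modal, so `fit_restarts` runs the fit from many derived seeds
(default 100, matching standard practice for this model family) and either
the best-bound run or a *representative* run is carried forward. The
representative run is chosen by computing, per run, the log-rank p-value of
DESNT-assigned samples versus the rest, estimating the mode of log10 p by
Gaussian KDE (Silverman bandwidth), and picking the run closest to that
mode — the selection is reproducible given the ensemble and clinical table.

### Choosing K

`select_n_signatures` scores each K by sample-wise 5-fold cross-validated
hold-out log-likelihood: the model is fitted on the training folds, each
held-out sample's γ is estimated by the projection E-step with parameters
frozen, and the sample is scored by Σ<sub>g</sub> log Σ<sub>k</sub>
θ̂<sub>k</sub> N(e<sub>g</sub>; μ<sub>gk</sub>, σ²<sub>gk</sub>). Both prior
modes are tabulated; the chosen K maximises the estimated-α curve, with
ties broken by the uniform curve and then by smaller K. For the CV sweep the
per-fold fits use a 1e-5 bound tolerance, at most 400 iterations and one
restart, with the estimated-α fit warm-started from the uniform fit of the
same fold; these reduced settings are for the selection scan only and do
not change the defaults of a final fit.

On tiny instances (one sample, two genes, K = 2) the exact log-evidence is
available by quadrature over the 1-simplex; tests assert that the bound
never exceeds it and that the projection-based hold-out log-likelihood
tracks it closely on moderate-overlap instances. The plug-in hold-out score
is *not* a lower bound — it can exceed the log-evidence when the posterior
over θ is broad — which is why the agreement check uses moderate
separations.

### OAS projection

`project_sample` decomposes one new expression profile into an existing
model's signatures with μ, σ², α frozen, iterating only that sample's
(Q, γ) to a fixed point (max |Δγ| < 1e-6, up to 500 iterations; mixtures
close to several signatures converge linearly and may need more — the cap
is configurable). The training cohort's own (Q, γ) is a fixed point of
these updates, so reprojecting training samples reproduces the full
decomposition (observed: per-signature Pearson r > 0.999, max absolute
deviation ≈ 0.04). Up to 10% missing genes are dropped from the sums (the
γ identity then uses the genes actually present); more is an error.

Cohorts are quantile-mapped per gene onto the training cohort's stored
reference quantiles before projection, because cohort-level batch
correction is unavailable when samples arrive one at a time. The mapping is
rank-based within the incoming cohort; a single sample therefore maps to
the per-gene reference median, so single-vector projection expects input
already normalised to the model's scale.

## Survival statistics

Kaplan–Meier, log-rank and Harrell's C are delegated to lifelines; the Cox
partial likelihood (Breslow ties) is maximised by statsmodels PHReg. The
Breslow baseline cumulative hazard is computed in-package, centred at the
covariate means, so nomogram predictions are an exact re-parameterisation
of the fitted model: covariate j at value x scores
100·β<sub>j</sub>(x − x<sub>ref,j</sub>)/max<sub>j'</sub>|β<sub>j'</sub>·range<sub>j'</sub>|
points (x<sub>ref</sub> = least-risk end of the observed range), and total
points map back through the linear predictor to S(t) at 1/3/5/7-year
horizons. Internal validation uses Harrell's optimism bootstrap (default
1000 resamples); calibration compares per-decile mean predicted S(60
months) with the in-bin KM estimate.

Covariate encodings are fixed: Gleason < 7, stage T1–T2 and negative
margins are reference levels; DESNT proportion and PSA are continuous.
Missing covariates are complete-case by default with an explicit
median/mode imputation flag (always warned).

Characterisation statistics: per-signature 2×2 χ² association tests use
Yates continuity correction (the R default for 2×2 tables); per-gene
differential expression is Welch's t with Benjamini–Hochberg adjustment,
with a cross-restart consensus filter (significant in ≥ 50% of ensemble
runs by default); pathway activation scores are mean per-sample z-scores of
gene-set members (sets with < 3 matched genes dropped by default), ranked
by absolute Pearson correlation with the DESNT proportion (top 20).

## The synthetic cohort generator

`simulate.simulate_cohort` draws data from exactly the generative model the
analysis assumes, plus a survival layer, so every stage is testable against
ground truth. Defaults define the package's standard study conditions:

| parameter | default | rationale |
|---|---|---|
| n_samples × n_genes × K | 150 × 300 × 4 | desk-scale cohort; enough genes that per-sample proportions are estimable |
| α | 0.1 per signature | sparse membership: most samples dominated by one signature, many carrying ≈ 0 of a given signature — matching the strongly skewed DESNT-proportion distributions in real cohorts |
| effect genes | 50% of genes, one signature shifted by 2σ | variance-ranked gene selection enriches for signature-differential genes |
| baseline means / σ | N(8, 2²), σ ∈ [0.5, 1.5] | log2 microarray intensity scale |
| hazard | 0.01/month · exp(ln 2 · θ<sub>risk</sub>) | planted log HR of ln 2 per unit risk-signature proportion |
| censoring | 20%, Uniform(0, T<sub>max</sub>) | T<sub>max</sub> solved numerically on the realised event times to hit the target censored fraction |
| binary label | 0.8 frequency in the risk signature, 0.2 elsewhere | planted over-representation for the χ² tests |

Clinical covariates (Gleason, PSA, stage, margins) are generated
independently of θ so the risk signature's effect is identifiable in
isolation.

What the generator does *not* emulate: probe-level microarray artefacts,
batch/series effects, normalisation pipelines (RMA/VST), gene–gene
correlation within a signature beyond the shared mean shift, non-Gaussian
expression noise, and clinical confounding (unless covariate–θ coupling is
wired in by hand). Passing tests therefore demonstrate correctness of the
inference machinery under the model's own assumptions, not robustness to
real-data violations of them.

## Known limitations

- Proportions estimated by projecting against a model fitted on a small
  separate cohort are mildly compressed toward the centre by that model's
  parameter error (projection with the true parameters shows essentially no
  compression, so the effect is training-set size, not posterior softness).
  A Cox coefficient fitted on such projected proportions is inflated by
  roughly the reciprocal of the compression slope. Fitting the decomposition
  on the cohort under analysis avoids this; no error-in-covariate
  correction is applied.
- At n = 1000 with a [0,1]-bounded proportion, Var(θ) can be at most ~0.19
  (and is ~0.13 under the default sparse Dirichlet), so the sampling
  standard error of the Cox log-HR, roughly 1/√(events · Var(θ)), is about
  0.1. A planted ln 2 is therefore recovered only to about ±1 SE ≈ ±15% per
  cohort; recovery claims tighter than that are not statistically
  attainable at this size.
- The hold-out score uses plug-in θ̂ rather than the marginal likelihood;
  it is accurate for moderately overlapping signatures but can exceed the
  true log-evidence for widely separated ones.
- Variational EM finds local optima; restarts mitigate but do not
  eliminate this (observed as occasional K = 3 selections on K = 4 data in
  the CV sweep).
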