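# Methods

This note documents the statistical machinery behind `graphsem`: the model,
the estimation choices, the survival hybrid, the synthetic-data generator,
and the known limitations.  It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Hypothesis graphs and compilation

A model is a graph over typed nodes (observed cohort variables or latent
factors) with three edge kinds: regression (`~`), factor loading (`=~`) and
covariance (`~~`).  Graphs serialize to JSON and to a canonical
structural-equation text in the lavaan syntax family, so models are portable
to other SEM software.  Validation is side-effect free: cycles are allowed
but flagged (estimation requires a stable path matrix), and survival nodes
may only be regression sinks — a directed edge *out of* overall survival has
no supported estimator here, and every survival model of interest points
into the endpoint.

Compilation targets the RAM parameterization: variables ordered observed
then latent, path matrix **A** (entry [i, j] is the coefficient on j→i),
symmetric matrix **S** (residual variances, exogenous variances,
covariances), filter **F** selecting the observed rows.  The implied
covariance is Σ = F(I−A)⁻¹S(I−A)⁻ᵀFᵀ.  Observed variables are numerically
coded: binary as 0/1, ordinal copy-number as its integer code −2…2, and a
k-level categorical as k−1 dummy columns (first label is the baseline).
Treating coded binary/ordinal predictors linearly in a covariance model is a
deliberate approximation — it matches how mutation indicators are normally
entered in cohort SEMs — and is the main reason estimates for such
predictors should be read as linear trends, not threshold effects.

Free covariances are added by default among all pairs of exogenous observed
variables, the standard convention that makes exogenous correlations part of
the model rather than misfit; a graph can opt out
(`"auto_covary_exogenous": false`), which is also how the variances-only
independence baseline is expressed internally.

## Estimation

The normal-theory ML discrepancy

F_ML = ln|Σ| + tr(S_obs Σ⁻¹) − ln|S_obs| − p

is minimized over free parameters by BFGS with the analytic gradient
dF/dθ_k = tr[(Σ⁻¹ − Σ⁻¹S_obsΣ⁻¹) ∂Σ/∂θ_k], where ∂Σ/∂θ_k follows from the
RAM identity for path and (co)variance parameters; an L-BFGS-B polish step
runs only if BFGS stalls above tolerance.  S_obs uses the n−1 denominator,
and n−1 is used consistently in χ² = (n−1)F_ML, RMSEA and the SE scaling.

Start values: free paths 0.1, free loadings 1.0, variances half the sample
variance (floored at 0.05), covariances 0.  Convergence is declared at
gradient max-norm < 1e−6 or relative F_ML change < 1e−10, capped at 500
iterations; non-convergence flags the result and withholds fit indices.
Standard errors come from the observed information — the finite-difference
Hessian of the analytic gradient scaled by (n−1)/2 — with z = estimate/SE
and two-sided normal p-values.  Standardized estimates (path × sd(src)/sd(dst)
on the model-implied metric) are reported alongside; z-scores are computed
on the unstandardized scale.

Missing data are handled by listwise deletion per fitted model (at least 3
complete samples, and more samples than observed variables, are required).
Latent scale is identified by fixing each factor's first loading to 1.
Degrees of freedom are p(p+1)/2 − q; df < 0 aborts before optimization.

Fit indices: with the variances-only baseline (closed form F_b = −ln|R|,
df_b = p(p−1)/2),

* TLI = ((χ²_b/df_b) − (χ²_m/df_m)) / ((χ²_b/df_b) − 1), reported unclipped;
* CFI = 1 − max(χ²_m−df_m, 0)/max(χ²_b−df_b, χ²_m−df_m, 0);
* RMSEA = √(max(χ²_m−df_m, 0)/(df_m(n−1)));
* SRMR = root mean square of the correlation-scale residuals over the lower
  triangle including the diagonal.

For a saturated model (df = 0) TLI and RMSEA are reported as not applicable.
The χ² p-value is intentionally absent from parameter tables: at n in the
hundreds-to-thousands it is dominated by sample size rather than model
adequacy.

Effect decomposition uses total = ((I−A)⁻¹ − I)[target, source] with
direct = A[target, source]; in cyclic models this is the convergent
geometric series, guarded by the spectral-radius check.  Factor scores use
the regression method, score = Ψ_f Λᵀ Σ̂⁻¹ (y − ȳ), which is linear in the
data and mean-zero over the fitting samples.

## Survival hybrid

A right-censored endpoint cannot be a column of a Gaussian covariance
model, so `graphsem` estimates edges into survival nodes in a second stage:
one Cox proportional-hazards model per survival node, with all graph
parents as simultaneous covariates and latent parents represented by their
factor scores.  This preserves the "controlling for" semantics — adding a
mediator or confounder parent changes the direct edge's z exactly as a
multivariable Cox adjustment — while respecting censoring.  The partial
likelihood uses the Breslow tie convention and is maximized by
Newton–Raphson with step-halving; SEs are the inverse observed information,
and |β| > 15 is treated as a separation flag.  Kaplan–Meier estimation and
the log-rank test delegate to lifelines.

Two limitations are accepted knowingly: factor scores enter the Cox stage
as if observed (their estimation uncertainty is ignored), and the SEM and
Cox stages are estimated sequentially, not jointly.

## Exploratory screening

The screen tests a seed variable against every candidate of the requested
sources, dispatching on the dtype pair: Pearson r (z from
t = r√((n−2)/(1−r²))) for continuous–continuous, point-biserial (the same
computation on the 0/1 coding, signed so positive means higher values in the
mutant group) for binary–continuous, Haldane–Anscombe-corrected log odds
ratio with Woolf SE for binary–binary (positive z = co-occurrence, negative
= mutual exclusivity), and the Cox Wald z when one side is survival.
Ordinal copy-number codes are treated as numeric, which is monotone-
sensitive and keeps the dispatch simple.  |z| is capped at 38, beyond which
the two-sided normal p underflows double precision, so rankings stay finite.
Benjamini–Hochberg q-values are computed within a run; degenerate
(zero-variance) candidates still count in the denominator, which is
conservative.  A precomputed store holds all pairs in a Parquet file,
computed in chunks so the identical code path serves a 50-variable fixture
or a full cohort; queries recompute q over the queried seed's records so a
store lookup is exactly an on-the-fly screen.

## Synthetic cohorts

`SimSpec` fixes the study conditions: a linear structural system with
Gaussian disturbances solved jointly (so stable cycles are supported),
optional latent factors with indicator loadings, Bernoulli mutation
indicators (marginal prevalence, or logistic in already-generated parents
for co-occurrence scenarios), ordinal copy-number codes produced by
quantile-thresholding a Gaussian copy signal to hit target code
frequencies, and exponential survival times with hazard
h₀·exp(Σβ·parent).  Censoring is an independent uniform horizon whose upper
bound is solved by bisection to match the requested expected censoring
rate.  Everything derives from one `numpy` Generator seed: the same seed
yields byte-identical fixture files.

Default condition choices used throughout the tests and the acceptance
script: cohorts of 300–2000 samples (the range of a typical per-cancer
cohort), mutation prevalence 0.3–0.4 (TP53-like), structural paths 0.6–1.2,
indicator residual sd 0.6 against unit factor variance, baseline hazard
0.01–0.02 per day with 20–30% censoring, and a CFA recovery study of 50
replicates at n = 2000.  These were chosen once as realistic cohort-scale
values; they are conditions, not tuning knobs.

What the generator does *not* emulate: expression heavy tails and batch
effects, linkage between copy number and expression dosage unless
explicitly specified, informative censoring, competing risks, and
mutation-signature structure.  Passing tests therefore demonstrate
correctness of the estimators under the stated generating model, not
robustness to every pathology of real cohort data.

## Numerical notes

* Fixture files write floats with `%.17g` and the readers parse with
  Python's correctly-rounded `float()`; write→load is exact, which the
  round-trip tests assert bit-for-bit.
* Hierarchical clustering for heatmap ordering uses average linkage on
  Euclidean distances with scipy's deterministic leaf order; ties and
  repeated calls are stable, and constant matrices fall back to input
  order with a warning.
* Row z-scaling uses the sample (n−1) standard deviation; constant rows
  become zeros with a warning rather than NaNs.
* Grouped mutation variables treat a single observed 1 as sufficient for
  the positive category under `any` even when co-members are missing; the
  output is missing only when every observed member is 0 and at least one
  member is unobserved (dually for `all`).
* Samples present in a cohort but absent from a MAF are wild-type, not
  missing, because MAFs enumerate only variant-bearing samples; the
  non-silent variant classes counted as "mutant" are the conventional set
  (missense, nonsense, frameshifts, in-frame indels, splice site,
  translation start, nonstop).
* Sample alignment across parts defaults to the sorted intersection for
  determinism; union-with-mask is available.

## Open design points resolved here

* Whether variables are standardized before fitting: they are not; both
  unstandardized and standardized estimates are reported, and z-scores are
  computed on the unstandardized scale.
* Whether exogenous observed variables covary freely: yes by default, with
  an opt-out, since fixing them to zero would count ordinary exogenous
  correlation as model misfit.
* How survival enters the model: the two-stage covariance-SEM + Cox hybrid
  described above, chosen over treating survival time as a Gaussian column
  (which would ignore censoring).
* CLI surface: the `km` verb stratifies by stored cohort variables;
  factor-score stratification requires a fitted model and is a three-line
  library call (`fit_graph` → `factor_scores` → `median_split`), so it is
  left to the library rather than duplicated as CLI state.
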