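# Methods

This note documents the models, the estimation machinery, the synthetic
data generators and the numerical choices behind `scrmpt`, in the spirit of
a package's statistical reference. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The SCR processing tree

The simplified conjoint recognition (SCR) paradigm yields, per participant
and condition, a 3×3 table of probe type × response counts over
(intact, related, unrelated). The tree model factorizes each row into a
multinomial whose category probabilities are sums of products of branch
probabilities:

* **Intact probes.** Verbatim retrieval (`Vi`) produces "intact". Failing
  that, gist retrieval (`Gi`) leads to a bias `a` for "intact" versus
  "related". Failing both, the participant guesses "old" with probability
  `b` and then "intact" with bias `ab`, else responds "unrelated".
* **Related probes.** Verbatim retrieval of the original pairing (`Vr`)
  correctly yields "related"; the gist and guessing branches mirror the
  intact tree with `Gr` in place of `Gi`.
* **Unrelated probes.** By construction of the paradigm the probe word
  shares no gist with studied material, so only the guessing branches
  apply: `b·ab`, `b·(1−ab)`, `1−b`. This is an explicit structural
  assumption of the package.

`ab` is a parameter (a second "intact" bias), not the product `a·b`; the
*greene* variant frees it, the *original* variant aliases it to `a`. The
reported configuration is the greene variant with the shared-gist
constraint `Gi = Gr = G`, which has six free parameters — exactly the six
degrees of freedom of one count table (two per probe row), so the
aggregate-data model is just-identified. Freeing `Gi ≠ Gr` on a single
table makes the model under-identified; the estimator allows it only for
multi-table settings and defaults to the constraint.

Intact and related subtrees each have six root-to-leaf paths (three
terminating in "intact", two in "related", one in "unrelated"); the
unrelated subtree has three. `enumerate_tree_paths` materializes them and
serves as the independent oracle for the closed forms in
`category_probabilities`; the test suite checks exact agreement on 1,000
random parameter vectors for both variants.

## Aggregate maximum likelihood

`MPTMaximumLikelihood` maximizes the multinomial log-likelihood
`Σ n_jk log p_jk(θ)` (multinomial coefficients omitted — they are constant
in θ) over the unit hypercube by L-BFGS-B on logit-transformed parameters,
from 10 random starts plus a neutral start at the hypercube center. Ties
within 1e−10 in log-likelihood break toward the lexicographically smallest
parameter vector. Standard errors come from the observed information
(central-difference Hessian on the logit scale, delta-method mapped to the
probability scale, `se_p = se_z·p(1−p)`); estimates with |logit| > 6 are
flagged as boundary solutions and reported without standard errors, since
the quadratic approximation is meaningless there. All-zero tables and
probe types with no trials are refused.

## Hierarchical Bayesian model

Participant-level probabilities arise through a probit link,

    θ_ip = Φ(μ_p + γ_p·educ_i + δ_ip),   δ_i ~ MVN(0, Σ),

with years of education mean-centered within the fitted cell. Each group ×
condition cell is fitted separately (pairing of fits for differences is the
caller's responsibility). Group-level probability-scale summaries are
`Φ(μ_p)` — the value at the covariate mean — with equal-tailed 2.5%/97.5%
credible intervals.

**Priors.** `μ_p ~ N(0, 1)` and `γ_p ~ N(0, 1)` (both scales exposed as
estimator parameters), and `Σ ~ inverse-Wishart(P+1, I)`. The
inverse-Wishart choice is deliberate: with `P+1` degrees of freedom the
implied marginal prior on every random-effect correlation is uniform on
(−1, 1), and conjugacy gives an exact Gibbs update of Σ given the offsets.
A half-Cauchy-scale/LKJ-style prior would need its own Metropolis moves on
P scales plus a correlation matrix, and in this model the covariance block
is what limits mixing per unit time; the conjugate step removes that
bottleneck at the cost of a mildly informative scale (the `I` in the
posterior scale matrix adds ~1/(ν+n−P−1) to each variance, negligible at
study sizes).

**Sampler.** Metropolis-within-Gibbs with, per sweep:

1. per-parameter random-walk updates of `μ_p` and `γ_p`;
2. a joint multivariate update of μ using the empirical covariance of
   recent warmup draws (classic adaptive Metropolis, 2.38/√P scaling,
   refreshed every 100 warmup iterations);
3. vectorized per-participant random-walk updates of each offset column
   `δ_·p` with elementwise accept/reject;
4. a likelihood-invariant *translation move* per parameter,
   `(μ_p, δ_·p) → (μ_p+ε, δ_·p−ε)`, accepted on the prior ratio alone —
   this decorrelates the group mean from the offset mean, the classic
   slow direction of centered hierarchical parameterizations;
5. the conjugate inverse-Wishart draw of Σ.

Proposal scales adapt during warmup by a Robbins–Monro recursion targeting
0.44 acceptance (0.25 for the joint move) with gain `min(0.25, 2/√t)`;
adaptation freezes at the end of warmup. Chains are initialized at the
probit of the pooled-data ML estimate plus N(0, 0.3) jitter, offsets near
zero, Σ = 0.16·I; initialization re-draws up to 10 times if the likelihood
is non-finite (with interior probits every tree category has positive
probability, so this is a guard, not an expected path). Chain streams
derive from a single root seed via `SeedSequence.spawn`; the seed is
mandatory.

**Geometry.** Default 4 chains × (3000 warmup + 3000 kept), roughly 35 s
per study-sized cell on one CPU. This is the geometry at which the maximum
split R-hat over all group-level quantities (μ, γ, and random-effect SDs)
stays below 1.05 across seeds on study-sized data; at 4 × (1000 + 1000)
the weakly identified random-effect SDs (of `Vr` and `ab`) still sit at
1.05–1.20. Reduced geometries are used in unit tests where only structural
behavior is under test.

**Diagnostics.** `split_rhat` implements the classic split-chain
Gelman–Rubin statistic (each chain halved, `sqrt(((n−1)/n·W + B/n)/W)`);
zero within-chain variance returns NaN ("undefined"), never 1. It matches
`arviz.rhat(..., method="split")` to six decimals in the tests.
`posterior_predictive_p` scores, for each retained participant-level draw,
the χ²-style distance `Σ (obs_mean − exp_mean)²/exp_mean` over the 3×3
mean-frequency table for the observed data and for one replicated dataset
simulated from that draw; p is the fraction of draws with
`T(rep) ≥ T(obs)`. `condition_difference` subtracts probability-scale
group draws (A−B) per parameter and flags credibility when the 95%
equal-tailed interval excludes zero.

## Behavioral indices

* **Inhibition index.** `IF = ACC·[2 − (RT_incons − RT_cons)/RT_cons]`.
  Accuracy is computed over all trials; condition mean RTs over correct
  trials only (standard Stroop practice; configurable via
  `rt_correct_only`). The index is invariant to rescaling both RTs by a
  common positive factor.
* **Response proportions.** Per-cell probe × response proportions with the
  named error cells R-I ("intact" responses to related probes) and R-U
  ("unrelated" to related probes); overall accuracy is the trial-weighted
  proportion of diagonal responses. A probe with zero trials yields NaN
  (missing), never 0.
* **AOI metrics.** Fixations shorter than 100 ms are dropped *before* AOI
  assignment; rectangles are closed (edge points count as inside) and must
  not overlap. FD/FF are per-AOI sums/counts; FD_P/FF_P divide by the
  total retained duration/count *including* fixations outside every AOI —
  published per-group AOI proportions sum to ≈0.95–0.97, implying non-AOI
  time in the denominator.
* **Effect sizes.** Pooled-SD Cohen's d with df-weighted variances and the
  pooled-variance two-sample t; zero pooled SD with unequal means signals
  an explicitly infinite d.
* **FDR.** Benjamini–Hochberg step-up via statsmodels, with input
  validation; hand-computed step-up cases are asserted in the tests.
* **Group codings** for downstream models: younger = 1 / older = 2;
  control = 1 / acute-training = 2.

## Serial mediation

Three OLS equations (`m1 ~ x`, `m2 ~ x + m1`, `y ~ x + m1 + m2`, each plus
covariates) give the paths a1, a2, d21, b1, b2, c′; the total effect c
comes from `y ~ x` (plus covariates) and satisfies
`c = c′ + a1·b1 + a2·b2 + a1·d21·b2` exactly in the fitted system (checked
to 1e−10). With `m2=None` the model reduces to the single-mediator form.
Standardization z-scores continuous variables; a binary predictor (two
distinct values, e.g. a 1/2 group code) is left as coded, so its
coefficients are *partially standardized* — the β convention of the source
analyses is not stated, and this choice is documented rather than hidden.
Percentile bootstrap (row resampling with replacement, default 5,000
resamples, seeded; re-standardized within each resample) gives CIs for the
indirect effects; significance is CI-excludes-zero. Designs with condition
number above 1e8 are rejected as collinear, naming the variables.

## Structural equation model

The model is held in RAM form: `v = A v + e`, `cov(e) = S`, implied
covariance `F(I−A)⁻¹S(I−A)⁻ᵀFᵀ`. Free parameters are loadings,
regressions, log-parameterized (residual) variances — keeping S's diagonal
positive by construction — and covariances among exogenous observed
variables. Identification fixes each latent's (residual) variance to 1 so
all loadings are free (`std_lv`, the default, matching one free loading
per reported standardized loading); a marker-variable option fixes the
first loading instead, and both give the same standardized solution and
χ². The ML discrepancy `F = log|Σ(θ)| + tr(SΣ(θ)⁻¹) − log|S| − p` is
minimized by L-BFGS-B from a deterministic start (loadings 0.7·sd,
variances at half the sample variances) with up to two jittered restarts;
a non-positive-definite Σ(θ) during the search returns a large smooth
penalty and is counted in `fit_indices_["n_nonpd"]`, never silent.

Fit indices: `χ² = (n−1)F_min`; `df = p(p+1)/2 − n_free`; CFI and TLI
against the independence baseline (`F_b = Σ log s_ii − log|S|`), TLI
truncated at 1 with the raw value retained; `RMSEA =
sqrt(max(χ²−df,0)/(df(n−1)))`; SRMR over the lower triangle (diagonal
included) of the correlation-scale residual matrix. Standardized
estimates rescale by the model-implied SDs of the full variable vector
(latents included); fitting raw-unit and z-scored data gives the same
standardized solution and χ² (scale invariance of ML, checked in tests).
Indirect effects are products of path coefficients along a chain, with a
delta-method SE (observed-information covariance `2/(n−1)·H⁻¹`) and a
nonparametric bootstrap refit as the cross-check.

## Synthetic data

Every generator emits the exact table schemas the estimators consume plus
a `SyntheticTruth` (generating parameters + seed); identical truth and
seed reproduce identical tables.

* **Memory trials.** Group-level probability presets named after the study
  cells (e.g. `older_gist`: Vi=.51, Vr=.03, G=.78, a=.51, ab=.13, b=.08)
  are mapped to probit means; participant probabilities add MVN offsets
  (default SD 0.4, exchangeable correlation 0.2 — the individual-level
  spread is not published, so this is a package choice held fixed) and an
  education effect (default slope 0; education ~ N(10.15, 2.29²) for older
  and N(15.68, 2.14²) for younger groups). Defaults: 40 participants ×
  (15, 18, 15) trials per probe per condition — two conditions give the
  paradigm's 30/36/30 per-participant totals.
* **Stroop trials.** 40 consistent + 40 inconsistent trials per
  participant; lognormal RTs (median 800 ms, CV 0.25) with a relative
  inconsistent-condition cost and Bernoulli correctness; participant-level
  jitter on accuracy (SD .03) and cost (SD .05). The truth records the
  implied IF = acc·(2 − cost); the older/younger presets (acc .94 cost .16
  vs acc .97 cost .07) imply IF 1.73 and 1.87.
* **Eye indicators.** One latent "interference" factor per participant,
  shifted by group (standardized path −0.32 by default, training coded 2),
  with four indicators FD, FD_P, FF, FF_P at standardized loadings
  (.96, .98, .99, .99) and noise variance 1−λ². Units are standardized by
  default or affinely rescaled to familiar ms/count/proportion anchors;
  the rescaled mode can additionally emit fixation-event streams whose
  `aoi_metrics` output reproduces the (integerized) indicators.
* **Path observations.** Standardized linear chain X→M1→M2→Y with
  residual variances topping each variable up to unit variance
  (coefficients implying variance > 1 are rejected). The default truth is
  the published chain (a1=−.38, a2=.51, d21=−.21, b1=−.10, b2=−.53,
  c′=−.33); x is a standard-normal score by default, with a balanced 1/2
  binary mode. In the eye-model structural mode, the R-I→ACC coefficient
  is not published and defaults to −0.40 as a free package choice — it is
  never treated as a reproduction target.

**What the generators do not emulate** — and hence what passing tests do
not show about real data: actual word/picture stimuli and their semantic
norms, serial-position and block structure, response times in the memory
task, non-normal education distributions, eye-tracker noise and drift,
raw 500 Hz gaze samples (only fixation events), and any dependence between
the memory, Stroop and eye modules beyond what the path models impose.
Recovery results certify the estimators under the model's own assumptions,
not the substantive findings.

## Problem sizes in tests and acceptance runs

The acceptance script averages the hierarchical recovery over 5 replicate
simulate-and-fit runs at the default 4 × (3000 + 3000) geometry: a single
40-participant draw carries ~0.06 sampling SD on the recovered group
means (the aggregate-MLE oracle confirms those fluctuations live in the
data, not the sampler), so the average reports the method's recovery
rather than one multinomial draw. The mediation and SEM recoveries use
500 replicates at the study sizes (n=79, n=59). The test suite uses one
2000+2000 fit plus ten reduced (2 × 500) fits for interval-coverage
calibration, and smaller geometries in structural unit tests.

## Known limitations

* With 15/18/15 trials per probe, `Vi`, `Vr` and `a` trade off against
  each other; recovered `Vi` for the older-gist cell averages ~0.05 below
  the generating value across data realizations (within the package's
  stated ±0.10 recovery tolerance) and `Vr`/`ab` random-effect SDs are the
  slowest-mixing quantities. This is a property of the design size, not of
  the sampler; it disappears as trials per probe grow.
* Group-level summaries are `Φ(μ)`, the median-participant probability,
  not the population mean `E[Φ(μ+δ)]`; with random-effect SD 0.4 the two
  differ by under 0.01 for mid-scale parameters but diverge near the
  boundaries.
* The SEM module covers recursive single-group models with free exogenous
  covariances — no multi-group models, mean structures, missing-data
  (FIML) estimation, or ordinal indicators.
* No information-criterion model selection for the tree variants; variant
  comparison is by likelihood and posterior predictive fit.
* The phantom-recollection tree extension is out of scope.
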