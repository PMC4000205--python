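# Methods

## Data model

The analysis table has one row per published classification model, clustered
by study.  A row carries eight study factors, the class-imbalance level of
the training set, a reported accuracy, and the number of samples n_eval the
accuracy was computed over.  Accuracy is converted to a grouped-binomial
outcome by rounding accuracy·n_eval to the nearest integer (halves up); the
reconstruction error is at most half a sample, i.e. |a/n − accuracy| ≤
0.5/n.  When a study evaluates by cross-validation, n_eval is the
training-set size; when an external test set is reported, n_eval is that
test-set size and must be supplied in the table.  Reported group sizes can
be converted to the imbalance level as max(sizes)/sum(sizes).

Categorical factors use reference (dummy) coding with the reference level
mapped to the all-zero pattern; the default reference is the most frequent
observed level, overridable per factor.  Numeric covariates (training-set
size, number of genes, imbalance) enter untransformed; a `log10_numeric`
switch applies log10 to the two counts for sensitivity analyses.  The
imbalance covariate enters as a raw, uncentred proportion.

## Random-intercept binomial model

For row j of study D: a_Dj ~ Binomial(n_Dj, pi_Dj) with logit(pi_Dj) =
x_Dj'β + b_D and b_D ~ N(0, σ²).  The marginal log-likelihood sums, over
clusters, the log of the binomial likelihood integrated against the normal
density of b_D.  The integral is approximated by adaptive Gauss–Hermite
quadrature: for each cluster the integrand's conditional mode b̂_D is found
by a damped Newton iteration (gradient tolerance 1e-11) and the quadrature
nodes are placed at b̂_D + sqrt(2/h_D)·z_k, where h_D is the negative
curvature at the mode.  One node (`quad_order=1`) is exactly the Laplace
approximation and is the default, matching the default of the mixed-model
software that popularized this model class; higher orders are exposed for
accuracy checks and converge to a dense brute-force integration of the same
integral (the test suite checks agreement to 1e-8 at 25 nodes).  At σ² = 0
the integral collapses and the code returns the plain grouped-binomial
logistic log-likelihood exactly.  Binomial normalizing constants are
included throughout so AIC values are comparable across software.

### Optimization

(β, log σ) is maximized jointly by L-BFGS-B with the **exact analytic
gradient** of the AGQ objective: the dependence of the quadrature centre and
scale on the parameters is differentiated implicitly through the mode
equation, so the gradient is exact at any quadrature order.  Internally the
design columns are rescaled to unit max-absolute-value for conditioning
(raw covariates such as gene counts otherwise produce a badly conditioned
Hessian); estimates are transformed back on exit.

Two boundary devices handle σ² = 0, which is common at realistic corpus
sizes:

* Before any interior search, the score of the marginal likelihood with
  respect to σ² at σ² = 0 is evaluated at the plain-logistic MLE:
  U = ½ Σ_D [(Σ_j (a−np̂))² − Σ_j np̂(1−p̂)].  If U ≤ 0 the boundary is the
  maximizer along the variance direction and the σ²=0 fit (the GLM MLE,
  via statsmodels) is returned directly.
* After the interior search, if the optimum lands at σ² ≤ 1e-5 or below the
  σ²=0 log-likelihood, the exact boundary fit replaces it.

Convergence is declared at a projected-gradient norm below 1e-5 (with up to
three seeded random restarts otherwise); tighter tolerances buy nothing at
the likelihood's curvature scale here.  AIC = −2·loglik + 2·(len(β)+1); the
+1 counts σ² even at a boundary estimate, so nested comparisons are
consistent across interior and boundary fits.

Standard errors come from the finite-difference observed information of the
marginal likelihood (central differences, relative step 1e-4), or from the
GLM information at the boundary.  Bulk refits inside the elimination loop
skip standard errors entirely (`se_method="none"`), since their tests are
likelihood-ratio based.

### Tests

Factor tests default to likelihood-ratio chi-square tests of nested fits,
which handle multi-degree-of-freedom factors uniformly; Wald tests on the
coefficient covariance are available as a configuration option and agree
with the LRT at large corpus sizes (checked within 0.02 at 500 studies).
P-values from either method are reported as-is; no multiplicity correction
is applied across factors.

## Inference procedures

**Null model**: intercept + imbalance + random intercept.  **Univariable
scan**: null + one factor per row; the imbalance row reports the null model
itself, tested against the intercept-only random-intercept model.
**Backward elimination**: from all eight factors, each step refits every
single-factor deletion, drops the factor with the lowest deletion AIC if it
beats the current model, and stops otherwise; the forced covariate is
exempt; AIC ties within 1e-6 break toward the smaller-df factor, then input
order.  A candidate whose refit fails is logged and excluded from that
step's comparison.  **Explained variation**: total = (σ²_null −
σ²_full)/σ²_null; factor k's relative contribution = (σ²_{−k} −
σ²_full)/σ²_null.  The denominator σ²_null is the default because it makes
the per-factor contributions commensurate with the total (they may still
sum above it when factors are correlated); the alternative denominator
(σ²_null − σ²_full) is a configuration switch.  σ²_null = 0 raises rather
than returning an undefined decomposition.  Note σ²_{−k} < σ²_full is
possible (removing a covariate can lower the variance estimate), so
negative relative contributions are reported, not clipped.  **Jackknife**:
the deletion unit is the study (cluster), not the model row — removing
single rows of a multi-row study would break the exchangeability the
procedure relies on.  Failed leave-out runs are excluded from the agreement
denominator and flagged.

## Synthetic corpora

The generator draws, per study: a random intercept b ~ N(0, σ²);
study-level factors (disease, question, platform), a training-set size, and
an imbalance level uniform on [0.5, 0.95]; then per model row: row-level
factors (CV technique, gene selection, classifier), a gene count, and a
correct-classification count Binomial(n_eval, invlogit(β'x + b)) with
n_eval equal to the training-set size.  Defaults mirror the published
corpus: 48 studies, a rows-per-study pmf {1: 0.80, 2: 0.15, 3: 0.04,
4: 0.01} calibrated to ≈61 rows per 48 studies, and factor prevalences
matching the published frequency table.  True coefficients are named by
design column (baseline = first vocabulary level), with imbalance's true
coefficient defaulting to zero so the imbalance *correction* is decoupled
from any real imbalance effect.  Factors are drawn independently by
default; a `confounding` knob correlates the CV technique with the medical
question to emulate the confounding visible in the real corpus.

What the generator does **not** emulate: publication bias, correlation
between factor levels and sample size, rounding/reporting heterogeneity of
published accuracies, or model rows sharing samples within a study beyond
the common intercept.  Passing recovery and stability tests therefore show
the estimator and the selection procedure behave correctly *under the
model's own assumptions*, not that the assumptions hold for any real
literature corpus.

Validation experiment sizes: parameter recovery uses 200-study corpora
(500 replicates in the test suite, 200 in the acceptance script); selection
stability uses 100-study corpora with one active factor (β = 1.5) among
seven nulls; the quadrature oracle uses 5 clusters of 2 rows.

## Benchmark stand-in table

The original row-level study table is not redistributable, so
`data/synthetic_study_table.csv` is constructed: the published row-level
marginals — 48 studies, 61 rows, and the six (CV × question) cells' counts
and mean accuracies — are hard constraints satisfied exactly; study-level
disease and platform counts match the published study-frequency table;
remaining fields are filled by a fixed-seed deterministic procedure, with
per-cell accuracies nudged in whole counts until each cell's mean rounds to
the published value.  Published *model outputs* (AICs, drop order, variance
decomposition) were deliberately not used in the construction: a fixture
tuned to reproduce model outputs would make every downstream check
circular.  Pipeline results on this table are internally consistent and
fully reproducible but are not estimates of the published corpus's values.

## Known limitations

* Laplace (1-node) likelihoods are approximate; for tiny clusters with
  small n_eval the approximation error can reach the first decimal of an
  AIC.  Raise `quad_order` to check sensitivity.
* σ² has no standard error reported (its Wald interval at a boundary is
  meaningless); recovery experiments report its bias and RMSE instead.
* The elimination's AIC comparisons use the same Laplace approximation as
  the fits; rankings between models closer than the approximation error are
  not meaningful.
* Only random intercepts are supported — no random slopes, crossed effects,
  non-logit links, or Bayesian estimation.
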