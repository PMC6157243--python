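# Methods

## Model

Every regression in the pipeline is a Gaussian linear mixed model with one
random intercept per family,

    y_if = x_if' beta + u_f + e_if,   u_f ~ N(0, s2_u),  e_if ~ N(0, s2_e),

which captures relatedness-induced correlation as a single shared family
component (no kinship/GRM covariance — see Limitations). Estimation is
restricted maximum likelihood. Because the model has a single variance
ratio lam = s2_u/s2_e, the REML criterion is profiled down to lam: for a
family of size n_f the marginal covariance is s2_e (I + lam J) with
closed-form inverse and determinant, so one criterion evaluation costs
O(F p²) after a single O(n p) pass over the data. The optimum is located
as the root of the criterion's analytic derivative (bisection bracket plus
Brent, xtol 1e-12), which makes the fitted ratio stable to near machine
precision — fits are reproducible under sample permutation and covariate
rescaling, which the test suite asserts. Variances are floored at 1e-10.
Fixed effects get Wald z tests (p-values clipped into (0, 1]); the
statsmodels MixedLM REML fit agrees with this engine to ~1e-6 on
coefficients and variance components and serves as the independent oracle
in the tests, alongside closed-form OLS at the lam = 0 boundary.

Lipids are strictly positive and analyzed as natural logarithms (log10
would only rescale coefficients). Methylation enters the models as the
beta value (fraction methylated, in [0, 1]), not the M-value, matching the
screen and TSLS regressions the procedure prescribes.

## Screening and the Bonferroni divisor

Each candidate CpG is tested with
`log(lipid) ~ beta_CpG + age + sex + center + smoking + (1 | family)`.
The significance gate is `bonferroni_alpha / bonferroni_n_tests`; the
divisor defaults to the number of CpGs actually tested for that trait and
is deliberately explicit configuration, because the count of trait-relevant
CpGs (e.g. 7 for triglycerides when 9 CpGs are on the candidate list) is a
study-design fact the data cannot infer. A CpG whose fit fails (constant
methylation column, too few complete cases) is reported with its error and
does not abort the remaining CpGs.

## Instruments

**Weighted score.** `raw_i = sum_j d_ij w_j / mean(w)`, standardized with
the (n-1) standard deviation ("mean 0, SE 1" is read as unit sample SD —
scaling by the standard error of the mean would inflate the score by
sqrt(n)). Before the formula is applied, each SNP is aligned to its risk
allele: a weight attached to the REF allele flips the dosage to 2 − d, and
a negative weight flips the SNP to its other allele so that all weights
are positive and the mean-weight denominator cannot degenerate under mixed
signs.

**LD proxies.** r² is the squared Pearson correlation of dosage vectors
over complete pairs, computed in-sample (no reference panel). A score SNP
with complete dosages is used directly; one that is genotyped but carries
missing dosages is replaced by the strongest complete same-chromosome
proxy exceeding the r² threshold (default 0.8), with the weight carried
over and the proxy's allele coding aligned to the sign of the dosage
correlation; a SNP absent from the genotypes is dropped and logged — with
in-sample LD there is nothing to correlate a missing SNP against.

**Elastic-net cis-meQTL selection.** Candidates are all SNPs within the
closed window [pos − 50 kb, pos + 50 kb] on the CpG's chromosome, minus
SNPs on the array probe. Methylation is first residualized on the
covariates and family intercept (marginal residuals; the family BLUP is
not subtracted). The net uses mixing parameter 0.5 and a 100-value penalty
path log-spaced down from the smallest penalty that zeroes all
coefficients (ratio 1e-4, or 1e-2 when p ≥ n); predictors are standardized
internally with the 1/n standard deviation and coefficients reported on
the dosage scale; fold assignment is a seeded permutation (default seed
123). The selected penalty minimizes the cross-validated MSE, ties going
to the largest (sparsest) penalty, and "significantly associated SNP" is
operationalized as "nonzero coefficient at that penalty" — penalized fits
have no standard p-values. The selection is deterministic given the seed
and invariant to candidate column order. An R glmnet fit at a fixed
penalty agrees with this implementation to ~1e-3 (glmnet's own convergence
slack; this implementation reaches a slightly lower objective value).
Cross-validation folds ignore family structure; since the residualization
has already removed the modeled family component this mainly risks mild
optimism in the CV curve, and is listed under Limitations.

The PRS-M reuses the weighted-score construction with the penalized
coefficients as weights (no unpenalized refit — the procedure builds the
score "using the same approach", and penalized weights are the
deterministic reading).

## Two-stage least squares

Stage 1: `exposure ~ score + covariates + (1 | family)`; the
single-instrument F statistic is the squared Wald z. F < 1e-6 raises a
weak-instrument error. Stage 2: `outcome ~ predicted_exposure +
covariates + (1 | family)`, where the prediction is the stage-1
*fixed-effect* linear predictor — family BLUPs are deliberately excluded
so outcome-correlated family variance cannot leak into the instrumented
exposure. Stage-2 designs are refused beyond a condition number of 1e10.
The stage-2 standard error of the predicted-exposure term is the naive
mixed-model SE, with no generated-regressor (Murphy–Topel/2SLS sandwich)
correction: the procedure is two literal regressions. Under the causal
null the correction term vanishes, so type-I error is unaffected; under a
true effect the SE is mildly optimistic (simulations here show ~5%).

With one instrument, no covariates and the variance ratio pinned at zero,
the stage-2 coefficient equals the Wald ratio cov(z, y)/cov(z, x) exactly;
the suite asserts this to 1e-6.

**Independence check.** The model
`outcome ~ score + covariates + prediction` is fit with the
*BLUP-inclusive* stage-1 prediction, and the score term's p-value is
reported. This is a deliberate design choice: the fixed-effect-only
prediction is an exact linear combination of the score and covariates, so
conditioning on it is rank-deficient by construction; including the family
BLUP (what an R `predict` on the stage-1 mixed model returns) contributes
the extra direction that identifies the model. The test is calibrated
under the global null and for a score orthogonalized against the
prediction, and has power against direct score→outcome paths; its
behaviour under a true causal effect is a limitation noted below.

## MR-Egger

Weighted linear regression of per-SNP outcome effects on exposure effects
(weights 1/se_out², intercept free), after aligning each SNP so its
exposure effect is non-negative; the intercept estimates the average
direct (pleiotropic) effect per variant. Standard errors carry a
multiplicative residual dispersion floored at 1 and p-values use the
normal approximation — defensible at small SNP counts and chosen for
determinism. Per-SNP effects come from paired mixed-model fits
(`exposure ~ SNP + covariates`, `outcome ~ SNP + covariates`), monomorphic
SNPs excluded; fewer than 3 usable SNPs leaves the slope unidentified and
is an error, so the driver skips Egger with a recorded note in that case.

## Synthetic data

The generator emulates the structure the analysis assumes — nuclear
families (founder pair plus 1–3 children by default), founder genotypes
binomial(2, MAF) per SNP with MAF ~ U(0.05, 0.5) (Hardy–Weinberg),
children by fair Mendelian transmission; no LD between distinct SNPs
beyond what transmission induces, with an optional duplicate-SNP injector
providing perfect proxies. Traits follow structural equations in causal
order: log-TG gets an intercept log(120 mg/dL), 20 lipid-SNP effects drawn
U(0.05, 0.25) per allele (strong instruments: F of several hundred at
n = 2000, comfortably past the F > 30 regime the recovery analyses
require, and enough spread in per-SNP effects to identify the Egger
slope), covariate effects, a family intercept (variance 0.2) and noise
(0.4). The focal CpG's M-value gets one cis-meQTL sized to explain 20% of
its non-covariate variance, optional causal coupling gamma·log(TG),
optional directional pleiotropy (a constant per-allele direct effect of
every lipid-score SNP), family variance 0.2 and noise 0.6; beta values are
the base-2 inverse logit 1/(1 + 2^(−M)), which keeps them strictly inside
(0, 1) without clipping. HDL-C is generated analogously with no coupling.
Default scenarios are acyclic — at most one of gamma (lipid→methylation,
M-value per unit log-TG) and delta (methylation→lipid, log-TG per unit
beta value) nonzero; a cyclic scenario requires an explicit flag and is
solved per sample by Gauss–Seidel fixed point to 1e-10.

What the simulator does *not* emulate: realistic LD maps, multi-generation
pedigrees, cell-type composition, batch effects, array measurement error.
Passing tests therefore demonstrate the statistical machinery under the
model's own assumptions plus Mendelian kinship, not robustness to the full
messiness of array data.

## Problem sizes used in the checks

Parameter recovery runs 200 replicates at n = 2000 (500 families of 4)
for the forward direction (gamma = −0.12 on the M-value scale, recovered
essentially unbiased; the pipeline's own reports stay on the beta-value
scale, where the same effect appears attenuated by the logistic
derivative). Null calibration runs 300 replicates at n ≈ 600; elastic-net
selection 40 replicates at n = 800 with 50 candidates; Egger power and
validity 100 replicates each at n = 2000 with 20 instrument SNPs and a
+0.1 per-allele pleiotropy shift. The acceptance script reruns smaller
versions of the same analyses (~2 minutes total).

## Known limitations

* **Kinship beyond the family intercept.** Transmission makes first-degree
  relatives' genotypes correlate at r = 0.5 at every locus, so a
  genotype-based score and a polygenic component of the outcome residual
  are jointly kinship-correlated inside families in a way a single family
  intercept cannot whiten. Measured consequence: reverse-direction null
  Wald z has sd ≈ 1.05 (rejection ≈ 5.9% at nominal 5% over 900
  replicates). A GRM random effect would fix this and is out of scope.
* **Independence test under a true causal effect.** Conditioning on the
  BLUP-inclusive prediction leaves the score's partialled direction
  proportional to the stage-1 BLUP, which carries between-family exposure
  variance; when the exposure truly affects the outcome the test
  over-rejects (it is calibrated under the global null and detects genuine
  pleiotropy). Interpret it as a diagnostic, not a calibrated test, when a
  causal signal is present.
* **lambda.min selects under pure noise.** The CV-minimum penalty has no
  null-model guarantee: on pure-noise residuals it returns a nonzero
  selection in roughly half of replicates (R cv.glmnet behaves
  identically). Downstream stages treat the instrument as data-derived and
  re-estimate its strength, so this inflates instrument availability, not
  causal type-I error; a 1-SE rule would be more conservative but is not
  the prescribed procedure.
* **One-sample MR.** Instrument selection, instrument strength and causal
  estimation all use the same sample; winner's-curse inflation of stage-1
  strength is not corrected.
* Stage-2 SEs are naive (above); weighted-median/modal estimators,
  multivariable MR and summary-statistic MR are out of scope.
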