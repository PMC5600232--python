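# Methods

This note documents the statistical model, the estimators, the synthetic
generator, and the numerical conventions used in `cqival`. It makes no
empirical claims beyond what the code computes.

## Data model

A survey dataset is one row per respondent with hospital ID, department
ID, specialty, 34 subscale items (30 four-point, coded 1–4; 4+6 yes/no
blocks coded 0/1 for the admission and discharge subscales), two 0–10
global ratings (department, hospital), and demographic covariates. Items
map onto nine fixed subscales; a subscale score is the mean of its items,
missing when fewer than half the items were answered.

Exclusion filters: respondents are dropped when the admission gate item
is not affirmative, or when fewer than half of the 34 core items are
answered (gate failures take precedence in the report counts; exactly
half answered is retained).

## Multiple imputation

Chained equations with predictive mean matching: independent chains, one
per imputation, visiting variables in ascending order of missingness.
Each univariate step draws regression coefficients from their posterior
(scaled-inverse-chi-square variance, normal coefficients) and matches
each missing case to one of its 5 nearest observed donors by predicted
mean. Convergence is screened with the potential scale reduction factor
R-hat over chain means (warning above 1.1; constant chains convention
R-hat = 1). Estimates computed per completed dataset are pooled with
Rubin's rules: total variance `T = W + (1 + 1/m) B` and
Barnard–Rubin-style degrees of freedom `(m-1)(1 + W/((1+1/m)B))^2`.

## Ordinal confirmatory factor analysis

Polychoric correlations are estimated in two steps: thresholds from the
inverse-normal of cumulative marginals, then the latent correlation by
bounded maximum likelihood, with the bivariate normal CDF evaluated via
Owen's T function. The correlation matrix is repaired to the nearest
positive semidefinite matrix when needed (logged).

The 9-factor model (each item loads on exactly one factor, factor
variances fixed to 1, factor correlations free) is fitted by diagonally
weighted least squares: minimize `F = sum_{i<j} w_ij (r_ij - sigma_ij)^2`
with `sigma = Lambda Phi Lambda'` and weights `w = 1/(1 - r^2)^2`, using
analytic gradients under L-BFGS-B. The model chi-square is `(N-1) F_min`;
with the unit-N weights above this has the standard asymptotic scale
(combining N-inclusive weights with an additional `(N-1)` factor would
inflate chi-square by a factor of N, so that combination is not used).
Degrees of freedom for the default 34-item map are 491. Fit is judged by
CFI, TLI and RMSEA with cutoffs CFI ≥ 0.95, TLI ≥ 0.95, RMSEA ≤ 0.06
("good" when at least 2 of 3 pass; "acceptable" at the relaxed 0.90/0.08
level; otherwise "poor"). TLI is undefined (reported as None, with a
warning) when the baseline chi-square per degree of freedom is ≤ 1.
Department-level CFA fits the same structure to Pearson correlations of
department-aggregated item means by the same least-squares machinery.

## Generalizability analysis

Variance components for the unbalanced nested designs p:d (respondents in
departments) and p:d:h (respondents in departments in hospitals) are
estimated by Henderson's Method 1 (analogous ANOVA), equating observed
sums of squares to their expectations with the standard unbalanced-design
coefficients; negative solutions are truncated to zero (recorded in the
result). On balanced designs the estimators coincide exactly with
classical nested ANOVA, which the test suite verifies.

D-study projections use `SEM_d = sqrt(sigma2_res/n_p)` for a department
mean and `SEM_h = sqrt(sigma2_d/n_d + sigma2_res/(n_d n_p))` for a
hospital mean, with G-coefficients
`G = sigma2_object / (sigma2_object + SEM^2)`. Minimum respondents per
department are searched on a grid of multiples of 50 (matching how such
planning numbers are reported); minimum departments on the integer grid.
SEM thresholds are 0.10 for four-point subscales and 0.025 for binary
subscales; the corresponding admissible noise band for a mean is
`1.96 * SEM * 2` (0.4 and 0.1 score units).

## Construct validity

Each global rating is regressed by OLS on the nine subscale scores plus
dummy-coded demographic covariates; with multiply imputed data the model
is fitted per completed dataset and pooled by Rubin's rules, with
significance read from the pooled 95% intervals. Rank-deficient designs
raise an error naming the aliased columns.

## Synthetic generator

Latent subscale scores are generated as
`z = mu + a_hospital + b_department + e_respondent`, with independent
normal hospital and department effects and respondent residuals
correlated across subscales via the Cholesky factor of a configurable
9×9 correlation matrix. Each item is a discretized congeneric indicator:
`x* = lambda * z_std + sqrt(1 - lambda^2) * eps`, cut at fixed normal
thresholds chosen to reproduce realistic category frequencies (subscale
means ≈ 3.4–3.5 on four-point scales, 0.6–0.7 on binary scales); the
default loading is `lambda = 0.8`. Global ratings are a linear
combination of latent subscale scores plus noise; covariates are drawn
from fixed marginal tables. Missingness can be injected as MCAR or as
MAR conditional on a covariate with per-level rate multipliers. The
generator returns the dataset together with a `GroundTruth` object
holding the configuration and the per-respondent latent scores.

Defaults (23 hospitals × 4 departments × 45 respondents; published-table
variance components and correlation matrix) are study conditions, not
tuned values.

### Scope and limitations

- **Recovery is defined on latents.** Discretizing through
  `lambda = 0.8` inflates the observed-score residual variance relative
  to the latent component (for a binary 10-item subscale with latent
  residual 0.059, the observed residual is roughly 0.11). Variance-
  component recovery is therefore asserted against the stored latent
  scores; minimum-sample answers computed from observed synthetic scores
  will differ from ones computed from the latent components by
  construction.
- **Department-level misfit is not reproduced.** The generator's
  department effects act on whole subscales, so department aggregates
  retain the 9-factor structure and fit well. A poor department-level
  verdict, as can occur with real data, is exercised through the
  fit-verdict logic rather than through simulation.
- Henderson Method 1 is a moment estimator: with few hospitals its
  hospital component is noisy and often truncated at zero under weak
  effects; tests average replicates accordingly.

## Numerical conventions

- All stochastic code takes explicit seeds (`numpy.random.default_rng`);
  pipelines and the CLI are byte-reproducible for a given seed.
- Polychoric and DWLS optimizations use bounded scalar search and
  L-BFGS-B with analytic gradients; Heywood factor-correlation matrices
  are projected back to valid correlations with a warning.
- Published variance components, shares, thresholds and response counts
  used as fixed reference inputs live in `cqival.reference`.
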