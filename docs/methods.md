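# Methods

## Model and estimation

The measurement model per gender is `y = nu + Lambda eta + eps` on the
standardized scale, `Sigma_g = Lambda_g Psi_g Lambda_g' + Theta_g`, with
factor variances fixed at one so `Psi_g` is a correlation matrix and
loadings are on the standardized metric. Estimation minimizes the
multi-group ML discrepancy

    F = sum_g (n_g/N) [ log|Sigma_g| + tr(S_g Sigma_g^-1) − log|S_g| − p
                        + (m_g − nu_g)' Sigma_g^-1 (m_g − nu_g) ]

over a parameter vector in which every cross-group equality constraint is a
shared index, so degrees-of-freedom accounting is exact by construction.
Sample covariances use the ML (divide-by-n) convention and the test
statistic is `chi2 = (N − G) · F_min`; this convention is used consistently
for all nested comparisons (absolute chi-square values are convention-bound
and are not comparable across packages).

Optimization is quasi-Newton (L-BFGS-B) with analytic gradients
(`dF/dSigma = Sigma^-1(Sigma − S − dd')Sigma^-1` chained to each parameter
block), an eigen-based start (principal-factor loadings, quartimin-rotated
and greedily matched to the spec's sparsity pattern), up to three L-BFGS
restarts from a stalled point (restarting resets the curvature memory), and
up to five jittered multi-starts before a convergence error. Convergence
requires a gradient max-norm below 1e-5; the discrepancy tolerance is 1e-13.
Non-positive-definite trial covariances are rejected by returning a large
objective value, which the line search backtracks away from. Negative
fitted residual variances (Heywood cases) are reported as warnings, never
silently bounded — mirroring the field's practice of removing the offending
variable instead of constraining it.

For unrotated (CFA-style) specs, a numerical Jacobian of the implied moments
is rank-checked at the solution; a deficient rank raises an
under-identification error. Rotated specs are deliberately fitted with the
loading pattern unconstrained beyond its symbolic zeros: the ML discrepancy
is invariant over the rotation orbit, so chi-square and df are exact, and
the direct-quartimin rotation is applied to the fitted solution for
reporting only.

## Degrees-of-freedom accounting for the invariance ladder

Each group contributes `p` means and `p(p+1)/2` covariances (208 total
moments for 13 variables, two groups). Rotated models carry `m(m−1)`
rotational identification constraints per *distinct* loading matrix: per
group in the configural model, once when loadings are constrained equal.
When loadings are equal but factor covariances are not (metric invariance),
the non-reference group's factor variances are freed — the factor scale is
only fixed in the reference group. These two rules reproduce the standard
multi-group ESEM ledger exactly: df 84 (M0), 97 (M1, equal means), 114 (M2,
equal loadings), 97 (M3, equal residual variances), 120 (M4, equal loadings
and factor covariances), 133 (M5, equal covariance matrices), and 107/111
for the constrained and reduced SEMs (101 and 97 estimated parameters).

## Robust scaling and the scaled difference test

Multivariate normality is screened with Mardia's multivariate kurtosis: the
mean of the squared Mahalanobis distances' squares against its exact-normal
reference `p(p+2)(n−1)/(n+1)`, standardized by the asymptotic variance
`8p(p+2)/n`. An empirical-CDF test of the distances against chi-square(p)
was considered and rejected: with estimated mean and covariance the
distances are dependent (their sum is a constant of the data), and
simulation shows such tests reject essentially never at any nominal level,
whereas the kurtosis form is near-nominal and has full power against heavy
tails — and excess kurtosis is precisely the regime the robust correction
addresses.

When normality is rejected (or on request), the chi-square is corrected by a
Satorra–Bentler-type mean-adjusting factor `c = tr(U Gamma)/df`, where
`Gamma` is the empirical asymptotic covariance of the stacked sample moments
(fourth-order moments, per group), and `U = V − V Delta (Delta' V Delta)^+
Delta' V` with `V` the normal-theory weight matrix at the estimates and
`Delta` the numerical moment Jacobian. The reported statistic is `chi2 / c`,
so multiplying a reported value by its scaling factor recovers the raw ML
statistic. Nested models are compared through
`c_d = (df_1 c_1 − df_0 c_0)/(df_1 − df_0)` and
`d-chi2 = |chi2_1 c_1 − chi2_0 c_0| / c_d`; the absolute value covers
comparisons where the more constrained model fits *better* (the constrained
SEM against the configural model). A nonpositive `c_d` is reported as an
invalid comparison, not clamped.

## Fit indices

RMSEA uses the printed per-degree-of-freedom discrepancy
`sqrt((chi2 − df)/(df (N − 1)))`, set to zero when chi2 < df, with the 90%
upper limit obtained by inverting the noncentral chi-square CDF at the 5th
percentile. The default is the single-group formula exactly as printed; a
`sqrt(G)`-inflated convention is available because the published table's
multi-group upper limits are not reproducible from the printed formula under
any convention we tried — the discrepancy is documented, not hidden. CFI
and TLI use the per-group zero-correlation baseline (diagonal covariance,
free means — fitted in closed form); CFI is clamped to [0, 1], TLI is not
(it can exceed 1). SRMSR is the root mean square of standardized
observed-minus-implied moment residuals over all non-redundant elements
including the diagonal, pooled over groups by sample-size weight. SBC uses
the full Gaussian log-likelihood (constants included) with `ln N` of the
total sample; its absolute value is therefore comparable within this package
only.

## Thresholds and defaults

| parameter | default | meaning |
| --- | --- | --- |
| MSA threshold | 0.60 | below: variable dropped (lowest first, recomputed each round; ties to earlier panel position) |
| loading threshold | 0.15 | constrained-SEM cells with smaller reference loadings fixed to zero |
| dietary threshold | 0.80 | dietary-intake correlation above which a residual covariance is added |
| dietary cap | 0.95 | pairs above are auto-excluded as collinearity hazards (logged) |
| reduction epsilon | 0.05 | fitted loadings/residual covariances below are zeroed in the reduced model |
| kurtosis / skew limits | 10 / 3 | natural-log transform rules (kurtosis index scale, Gaussian reference 3) |
| alpha | 0.05 | per-test level; no multiplicity correction by default (a Bonferroni option exists) |

The detection-limit rule (drop a variable when more than half its values sit
below 0.1 weight%) runs before the MSA filter: log-transforming a
mostly-censored variable only normalizes noise. Missing values are handled
by listwise deletion with a logged count. Subjects of unrecorded gender are
refused by the scorer.

Two conventions deserve attention. First, the log-transform scale: the
published log-scale standardization constants (−6.38, −5.04) correspond to
logging the weight *fraction* (percent/100), not the percent; the package
defaults to the fraction scale and exposes a percent-scale option (the two
give identical z-scores when constants are shifted consistently, which the
bundled loader does). Second, the constrained models fix four standardized
gender mean contrasts at zero (C22:6n3, C20:4n6, C16:0, C18:1t — the
contrasts not distinguishable from zero); this is what makes the constrained
model's count 101 estimated parameters.

## Factor signs and explained variance

Loading signs are arbitrary up to a joint column/Psi flip. Fitted solutions
are reported with each factor's largest-magnitude loading positive (flips
shared across groups whenever loadings or factor covariances are
constrained equal); an explicit flip utility reproduces the published
convention of orienting the PUFA factor so n3 acids load positively. For
simulation recovery studies the indeterminacy is resolved against the
generating solution (`align_signs_to`) — necessary because the bundled PUFA
column's two largest magnitudes (0.847 and −0.837) are nearly tied, so the
magnitude convention itself flips under sampling noise.

Per-variable communalities are `lambda_j' Psi lambda_j`; per-factor shares
attribute `[Lambda' Lambda Psi]_kk / p`. The claim that the first dimension
explains about 30% of total variance refers to the *first extracted
dimension*: the leading eigenvalue of the implied correlation matrix over p
(0.29 men, 0.32 women with the bundled parameters). The loading-based
per-factor share is smaller (about 0.24) because it splits cross-factor
covariance symmetrically; both quantities are exposed.

## The synthetic-data generator

The generator draws `eta ~ N(0, Psi_g)`, `eps ~ N(0, Theta)` and forms
`z = nu_g + Lambda_g eta + eps` with the bundled published parameters by
default, at the study's group sizes (1434 men, 1762 women). Raw-scale
output back-transforms through the published means/SDs; the two log-scale
acids exponentiate, so their raw values are strictly positive. Heavy-tail
contamination replaces the Gaussian draw with a multivariate t rescaled to
the same covariance, so only fourth and higher moments change — the regime
that drives the robust scaling above one. Group-equalize flags copy the
reference group's parameter blocks for type-I-error studies. Optional
nuisance columns emulate the acids the published screening excluded
(C22:5n3 planted at correlation 0.39 with the PUFA factor, C18:2n6 weakly
at 0.10, plus pure-noise columns the MSA filter should discard).

What the generator does *not* emulate: compositional closure (weight%
summing to 100), assay detection-limit censoring, skewness beyond what the
two log-normal coordinates induce, and any real dietary-intake structure —
the bundled dietary correlation matrix is a labelled synthetic stand-in
whose only guaranteed property is that exactly the known 14 pairs exceed
r = 0.80 (with the near-collinear trans pair at 0.98). Passing tests
therefore validate the machinery — accounting, estimation, calibration,
scoring — on data satisfying the model's assumptions; they do not re-verify
the published substantive estimates on the real cohort, which is
access-controlled.

One honest negative: with the published log-scale SDs (0.41, 0.48), a
log-normal variable has skewness about 1.3–1.4 and kurtosis index about
6–8, *below* the >3/>10 transform thresholds — so on generator output the
moment rules alone do not flag the two log acids. Real assay data evidently
had heavier tails. The pipeline therefore accepts `transforms="panel"` to
use the panel's known log flags, and the moment rules are unit-tested on
distributions that genuinely cross the thresholds (log-normal sigma = 1,
closed-form skewness 6.18).

## Problem sizes used in the test suite

Simulation tests run at the study's group sizes (1434/1762) where the claim
concerns the study conditions: 100 replicates for loading recovery (each
free loading's mean within 3 Monte-Carlo SEs of its published value) and
200 group-equalized replicates for type-I calibration of H1–H5 (3-sigma
binomial band around 0.05). Law-of-large-numbers checks of the generator
use 1e5–1.5e5 subjects per group; oracle-equivalence checks (scoring
weights, robust scaling, R's `factanal` for ML EFA) use small fixed
problems where the oracle is exact. All randomness is seeded; the whole
suite runs in about a minute on one CPU.

## Known limitations

- Absolute chi-square, SBC, SRMSR, CFI and TLI of the published table
  cannot be reproduced without the access-controlled cohort data; only
  degrees of freedom, parameter counts and the printed difference-test
  arithmetic are reproducible, and only those are asserted.
- The ESEM equality machinery is approximated by fitting rotated models
  unconstrained on the rotation orbit and rotating the reference solution;
  df accounting is exact, but rotated *estimates* under cross-group
  equality may differ from a simultaneous-rotation implementation.
- Which single loading the published reduction removed is not identified in
  print; the bundled pre-reduction pattern places it at the men's
  C18:0 × TRANS cell (parameter counts are invariant to the placement).
- Eigenvalue-over-one retention on sampled data occasionally returns four
  dimensions at n ≈ 3200 (the fourth population eigenvalue sits near one);
  the pipeline warns on group disagreement and takes the larger value, and
  the dimension can be fixed in configuration.
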