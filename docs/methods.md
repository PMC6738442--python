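# Methods

This note documents the statistical procedures implemented in `ccamode`,
the choices made where a published recipe leaves details open, and what
the synthetic validation does and does not demonstrate.

## Cohort emulation

The generator (`ccamode.synthetic`) draws every variable from a factor
model with confound contamination:

    x_ij = a_j z_i + Σ_k c_jk g_ik + ε_ij,

with latent mode score z, four confounds g_k (age, absolute motion,
relative motion, head size) and noise ε all i.i.d. standard normal. For a
single mode with unit noise, the best linear combination of a variable set
correlates with z at ρ = √(aᵀa/(aᵀa+1)), so the population first
canonical correlation between the two sets is ρ_x·ρ_y;
`strengths_for_canonical_correlation` inverts this map. Planted loadings
are drawn i.i.d. Gaussian on a randomly chosen loaded subset (default 30%
of each set) and rescaled to the requested total norm — a deliberately
neutral choice; concentrating the same norm on fewer variables makes each
loading individually easier to estimate.

Defaults mirror the emulated study design: 193 subjects; 453 IDPs in five
modality blocks (SIENAX 10, FIRST 15, FAST 139, BIANCA 1, TBSS 288 = 48
tracts × 6 diffusivity indices); 70 non-IDPs (cognition 31, demographic 8,
health 22, lifestyle 9); per-variable polarity flags mark lower-is-better
measures (reaction times, error counts, white-matter hyperintensity load,
diffusivity indices). Missingness is missing-completely-at-random, 0 for
imaging (acquisition was complete in the design being emulated) and 0.2
for non-IDPs (survey "unknown" fractions reach ~30%); MCAR is assumed
because completion-validity tests need a known mechanism. A handful of
survey items can be made ordinal by equal-mass thresholding
(`ordinal_levels`); the analysis treats everything as rank data anyway.
One sentinel variable per confound receives a strong loading so that
confound leakage is present by construction and its removal is testable.

The IQ panel uses a shared-factor model in which all four waves (ages
~11, ~20, ~57, ~63) load √0.71 on a common factor, so the wave-20/wave-57
population correlation is 0.71 (hence R² = 50.4% for the wave-57-on-
wave-20 regression).

What the generator does **not** emulate: within-block spatial correlation
of imaging measures, realistic covariance beyond the planted mode(s) and
confounds, non-Gaussian raw distributions beyond the thresholded items,
and informative missingness. Passing tests therefore demonstrate
correctness of the statistical machinery under a known truth, not
robustness to every feature of real phenotype data. One visible
consequence: 30 principal components explain only ~34% of synthetic IDP
variance, versus ~70-78% in real imaging data whose variables are heavily
inter-correlated.

## Preprocessing

Order: quantile normalization → confound regression → (multivariate path
only) soft-impute. The univariate screen instead uses pairwise-complete
observations, so imputation never manufactures evidence for a single
correlation. Confound regression precedes imputation, following the order
in which the steps are described in the recipe this implements; the
alternative order is possible by calling the operations directly.

* **Quantile normalization** uses the Blom offset Φ⁻¹((r − 3/8)/(m + 1/4))
  with average ranks for ties — the standard convention, bounded away from
  0 and 1. It makes every downstream Pearson correlation a function of
  ranks only (invariant to monotone transforms of raw measurements) and
  is exactly idempotent.
* **Deconfounding** regresses each column on [intercept | 4 quantile-
  normalized confounds] by least squares (observed rows only for columns
  with missing entries); output correlations with every confound are < 1e-10.
  A rank-deficient design falls back to a pseudoinverse fit with a warning.
* **Soft-impute** iterates fill → SVD → soft-threshold singular values by
  λ → restore observed entries, until the relative Frobenius change drops
  below `tol` (default 1e-6, `max_iter` 500). λ defaults to an internal
  grid search (0.02-0.4 × top singular value) minimising held-out error on
  5% of observed entries masked for validation. Small target λ is reached
  through a warm-started geometric continuation path from λ₀ = σ₁/2,
  which keeps the iterate effectively low-rank; a direct fixed-point
  iteration at λ ≈ 0 is the identity map and would stall. Observed
  entries are never modified.

## Change scores and extreme groups

Residualized change is the standardized residual of follow-up on baseline
(simple OLS; residuals divided by their sample SD), exactly uncorrelated
with baseline. Raw-difference scores z-score each wave on complete pairs
(population SD, ddof = 0) and subtract later minus earlier; under
imperfect reliability these are negatively correlated with baseline
(regression to the mean), which is why selection uses the residualized
form. Selection excludes |z| > cutoff (default 3) and by default splits
all retained subjects at z = 0 (improvers strictly positive); `n_top` /
`n_bottom` instead retain only the extremes, emulating true
extreme-groups sampling from a larger screening panel. Change-adjusted
correlations residualize both variables on [intercept | change score] and
test the residual correlation on n − 3 degrees of freedom.

## Mass-univariate screen

All pairs get Pearson r on pairwise-complete observations with two-sided
p from t = r√((n_eff−2)/(1−r²)); pairs with fewer than 4 complete pairs
or a constant variable are flagged untestable and excluded from the
multiplicity count. Bonferroni flags p ≤ α/m (m = testable pairs;
an effective-m override exists for users who want a dependence-adjusted
denominator) and Benjamini-Hochberg supplies FDR flags; BH can never yield
fewer discoveries than Bonferroni. P-values are floored at the smallest
positive double so −log₁₀ p stays finite. The subgroup-consistency check
recomputes each FWE-significant correlation within improvers and
decliners and flags sign reversals of both subgroup correlations against
the pooled one (Simpson's-paradox screen). Manhattan export orders pairs
by y-variable, carries the block colour key, and draws the FDR line only
when FDR adds discoveries beyond Bonferroni.

## CCA with permutation familywise inference

PCA uses a column-centered SVD; scores are left singular vectors scaled
by singular values. The default d = 30 carries a d ≤ n/6 guardrail
warning. CCA is computed by QR of each centered score matrix followed by
SVD of Q_xᵀQ_y — numerically equivalent to the generalized eigenproblem
Σ_xx⁻¹Σ_xyΣ_yy⁻¹Σ_yx (the test suite checks agreement with a brute-force
eigensolver to 1e-8) but stable under ill-conditioning. Rank-deficient
inputs are trimmed to effective rank via pivoted QR with a warning.
Variates have unit sample variance; signs are fixed by making the
largest-magnitude weight of each A-column positive, with B following so
corr(U_i, V_i) = +R_c,i.

The permutation test shuffles rows of one matrix (which one is immaterial
by symmetry) and records the largest canonical correlation of each of the
`n_perm` shuffles; p_fwe,i = (1 + #{null max ≥ R_c,i})/(n_perm + 1) — the
+1 convention avoids zero p-values. Because column means are invariant
under row permutation, each null draw costs one small matrix product and
SVD on the precomputed orthonormal bases rather than a full refit.
Permutations are applied in a canonical subject order (sorted IDs), so
identically reordering the subjects of both tables leaves p-values
bit-identical, not just equal in distribution.

Post-hoc loadings are correlations between polarity-adjusted variables
and the variates, computed against the deconfounded pre-PCA tables
("original variables"; a flag allows raw). The global mode sign is chosen
so the cognition-subdomain mean loading is positive — the
positive-negative orientation in which favourable qualities load
positively. Loadings with |r| < 0.2 carry `reported = False`. Subdomain
importance sums squared loadings of each sign and divides by the
subdomain's total member count, so an all-positive subdomain's bar equals
its plain mean r². Subgroup analyses correlate each subgroup's rows of the
whole-group variates against that subgroup's variables, and Tucker
φ = Σa_ib_i/√(Σa_i²Σb_i²) (pairwise deletion of missing loadings)
quantifies cross-group congruence.

## Numerical and design notes

* Per-stage seeds derive from the master seed through `SeedSequence`
  spawn keys (counter-based), so toggling one pipeline stage never
  perturbs another stage's random stream; all derived seeds stay below 2³¹.
* TSV is the single tabular dialect (tab-separated, header, subject ID
  first, "NA"/empty = missing); every output file opens with a config-hash
  comment line.
* Validation problem sizes: oracle-equivalence and worked-example checks
  run on small exact instances; calibration uses 200 null datasets at
  n = 193, d = 30 with 500 permutations; study-scale recovery uses the
  full 453/70 manifest over 20 seeds with 999 permutations; univariate
  power uses 50 seeds of the full screen. The permutation type-I error is
  checked against the 95% binomial interval around 0.05.

## Known limitations

* With the planted mode spread over ~136 of 453 IDPs at population
  canonical correlation 0.75 and n = 193, individual IDP structure
  loadings (~0.15) sit at the scale of the 1/√193 sampling noise of a
  correlation estimate, so the IDP-side loading *vector* can only be
  recovered up to a correlation of roughly 0.6 — an information limit of
  the design, not of the estimator. The denser non-IDP side recovers at
  ~0.85. Subgroup congruence behaves correspondingly (high for non-IDPs,
  lower for IDPs) at these sample sizes.
* In-sample R_c,1 overestimates the population value at n = 193, d = 30
  (overfitting is upward); the permutation null accounts for this in
  inference, but the point estimate should be read with that bias in mind.
* Plain Bonferroni over 31,710 rank-based tests is conservative under
  inter-variable dependence; the effective-m override exists but no
  automatic effective-number-of-tests estimate is provided.
* No sparse or regularized CCA, no confidence intervals on R_c, and no
  more-than-two-set extension.
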