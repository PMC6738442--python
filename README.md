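# ccamode

Statistical machinery for relating structural brain imaging-derived
phenotypes (IDPs) to cognitive, demographic, health and lifestyle measures
(non-IDPs) in a midlife cohort: mass-univariate correlation screening with
multiple-testing control, and PCA-reduced canonical correlation analysis
(CCA) with max-statistic permutation familywise inference. A synthetic
cohort generator with a planted latent brain-behavior mode makes every
stage testable without access to restricted cohort data.

Intended for biostatisticians and imaging-epidemiology researchers who
want a reproducible, fully tested implementation of this analysis recipe —
including the preprocessing conventions (rank-based inverse normal
transform, confound regression, soft-impute matrix completion) and the
extreme-groups subject-selection step that typically precedes it.

## The model

Given a subjects × IDP matrix **X** (453 variables across five MRI
modality blocks) and a subjects × non-IDP matrix **Y** (70 variables
across four subdomains), each column is quantile-normalized
(Blom: Φ⁻¹((r − 3/8)/(m + 1/4))), residualized on four confounds (age,
absolute/relative scanner motion, head size), and — on the multivariate
path — completed by soft-impute (iterative SVD with soft-thresholded
singular values). Both matrices are compressed to their top *d* = 30
principal-component scores, and CCA finds weights A, B for the variates

    U = X_p A,   V = Y_p B,

maximising R_c,i = corr(U_i, V_i) mode by mode. Significance is assessed
by permuting the rows of one matrix 10,000 times and comparing every
observed R_c against the permutation null distribution of the *largest*
canonical correlation, which yields familywise-error-corrected p-values
over all 30 modes. Post-hoc, modes are interpreted through structure
loadings (correlations between polarity-adjusted observed variables and
the variates, reported when |r| ≥ 0.2), per-subdomain importances (mean
squared loading split by loading sign), and Tucker congruence between
subgroup loading vectors.

The univariate path screens all 453 × 70 = 31,710 variable pairs with
Pearson correlations on pairwise-complete observations (p from the exact
t transform), controlling FWE by Bonferroni and FDR by Benjamini-Hochberg,
with Manhattan-plot export.

Subject selection uses residualized change: the standardized residual of
follow-up IQ regressed on baseline IQ (uncorrelated with baseline by
construction), with |z| > 3 excluded and the remainder split into
improvers and decliners. Raw-difference change scores (normalized
later-minus-earlier wave) are available as adjustment covariates.

## Worked example

```python
from ccamode import (GeneratorConfig, generate_cohort, pairwise_correlations,
                     multiple_testing, cca_analysis)
from ccamode.preprocess import preprocess_tables
from ccamode.synthetic import strengths_for_canonical_correlation

# synthetic cohort: 193 subjects, 453 IDPs, 70 non-IDPs, one latent mode
# planted at population canonical correlation 0.75
mx, my = strengths_for_canonical_correlation(0.75)
cfg = GeneratorConfig(seed=7, mode_strength_idp=mx, mode_strength_nonidp=my)
bundle = generate_cohort(cfg)

idp, _ = preprocess_tables(bundle.idp_table, bundle.confounds)
nonidp, _ = preprocess_tables(bundle.nonidp_table, bundle.confounds, impute=True)

records = pairwise_correlations(idp, nonidp)
report = multiple_testing(records, alpha=0.05)
print(f"{len(records)} pairwise tests, Bonferroni p <= {report.bonferroni_p:.3g}, "
      f"{report.n_pass_fwe} FWE-significant")

analysis = cca_analysis(idp, nonidp, d=30, n_perm=2000, seed=7,
                        loading_tables=(idp, nonidp))
print(f"rc_1 = {analysis.cca.rc[0]:.3f}, p_fwe = {analysis.cca.p_fwe[0]:.4f}")
top = analysis.loadings_nonidp.loc[analysis.loadings_nonidp["loading"].abs().idxmax()]
print(f"strongest non-IDP loading: {top['variable']} "
      f"r = {top['loading']:.2f} (r2 = {top['r2']*100:.1f}%)")
```

prints

```
31710 pairwise tests, Bonferroni p <= 1.58e-06, 0 FWE-significant
rc_1 = 0.764, p_fwe = 0.0040
strongest non-IDP loading: health_007 r = 0.60 (r2 = 35.9%)
```

The planted mode spreads its signal thinly over ~30% of the variables, so
no single pair survives the Bonferroni threshold of 0.05/31,710 — yet the
multivariate test detects the mode decisively (estimated first canonical
correlation 0.76 against a planted population value of 0.75, familywise
p = 0.004 from 2,000 row permutations). The strongest structure loading
identifies one of the truly loaded variables, explaining ~36% of its
variance. This univariate-blind / multivariate-visible contrast is exactly
the regime the method is designed for.

A command-line interface mirrors the library:

```
ccamode simulate --seed 7 --out cohort/
ccamode run --input-dir cohort/ --seed 7 --nperm 10000 --d 30 --out results/
```

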