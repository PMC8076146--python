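# mrkit

Two-sample Mendelian randomisation (MR) from GWAS summary statistics, for
epidemiologists who want the full inference chain of a "genetic liability to
an exposure vs a panel of disease outcomes" study as a tested, scriptable
Python package: instrument selection, allele harmonisation, the standard
estimator battery, pleiotropy and heterogeneity diagnostics, multivariable
adjustment, and a ground-truth simulator to validate all of it.

## What it computes

Given per-SNP associations with an exposure (γ̂_j ± σ_xj) and an outcome
(Γ̂_j ± σ_yj), harmonised to common effect alleles, `mrkit` estimates the
causal effect θ in the pathway model Γ_j = θ γ_j + α_j:

- **Wald ratio** per SNP: Γ̂_j/γ̂_j, SE σ_yj/|γ̂_j|;
- **IVW** (headline): weighted regression through the origin with weights
  1/σ_yj², multiplicative random effects (SE × max(1, √(Q/df))), Cochran's Q
  and I² heterogeneity;
- **Weighted median**: consistent when ≥ 50% of the weight comes from valid
  instruments; parametric-bootstrap SE;
- **MR-Egger**: regression with intercept; the slope corrects for
  directional pleiotropy (under InSIDE), the intercept tests for it;
- **Multivariable MR**: joint regression on several exposures' betas for
  direct effects conditional on mediators/confounders;
- instrument strength (per-SNP and score **F statistics**, variance
  explained), LD **clumping** (r² < 0.01 within 10,000 kb by default), and a
  Bonferroni-tiered forest table (`significant` / `suggestive` / `limited`).

Binary-trait effects are log-odds; results are reported as OR with 95% CI
per unit log-odds of exposure liability.

## Worked example

Simulate a two-sample study with a known causal effect θ = 0.25
(OR = e^0.25 ≈ 1.28) and analyse it:

```sh
mrkit simulate --preset small-fast --seed 7 --theta 0.25 --out demo
mrkit estimate --exposure demo/exposure.tsv --outcome demo/outcome.tsv --seed 1
```

prints

```
IVW      OR 1.253 (95% CI 1.171, 1.340) p=5.38e-11 I2=0.0% n_snps=15
W-median OR 1.264 (95% CI 1.148, 1.391) p=1.83e-06
MR-Egger OR 1.421 (95% CI 1.114, 1.814) p=0.00472; intercept -0.0066 (p=0.291)
```

All three estimators bracket the generating OR of 1.28: 15 of the 50
simulated SNPs reach genome-wide significance in the (deliberately small)
exposure GWAS and act as instruments; I² = 0 says the per-SNP estimates are
mutually consistent, and the Egger intercept near 0 (p = 0.29) shows no
evidence of directional pleiotropy — as it should, since none was simulated.
`demo/truth.tsv` holds the generating per-SNP effects for comparison.

The same analysis is available as a library:

```python
import mrkit

params = mrkit.preset_params("insomnia-like", seed=7, theta=0.18)
exposure, outcome, truth = mrkit.simulate_two_sample(params)
h = mrkit.orient_positive_exposure(mrkit.harmonize(exposure, outcome))
est, het = mrkit.ivw(h)                      # headline random-effects IVW
wm = mrkit.weighted_median(h, seed=1)        # sensitivity analyses
egger = mrkit.mr_egger(h)
```

Full multi-outcome studies run from a YAML config
(`mrkit run --config study.yaml`) and write a forest-style TSV per
outcome × method, SNP-level tables, drop logs and a resolved-config copy.
See `docs/methods.md` for the model, assumptions and design choices.

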