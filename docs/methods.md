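# Methods

## The problem

Two-sample Mendelian randomisation (MR) estimates the causal effect of an
exposure on an outcome from GWAS summary statistics alone. SNPs robustly
associated with the exposure serve as instrumental variables: because
genotypes are fixed at conception, the SNP–outcome association is protected
from confounding and reverse causation, provided the instruments affect the
outcome only through the exposure. `mrkit` implements the full inference
chain for a study of the "genetic liability to a binary exposure vs many
binary outcomes" design — e.g. insomnia liability against a panel of
cardiovascular diseases — at the summary-statistic level.

## Model and estimators

For SNP *j*, let γ̂_j (SE σ_xj) be the SNP–exposure association and Γ̂_j
(SE σ_yj) the SNP–outcome association, both log-odds per effect allele after
harmonisation. Under a linear pathway model Γ_j = θ γ_j + α_j, where θ is the
causal effect per unit log-odds of the exposure and α_j a direct
(pleiotropic) effect, zero for valid instruments.

* **Wald ratio**: θ̂_j = Γ̂_j / γ̂_j with first-order delta SE σ_yj/|γ̂_j|.
  The second-order term involving σ_xj is deliberately omitted: with
  hundreds of genome-wide-significant instruments the per-SNP F is large and
  the correction is negligible, and the IVW weights below then reduce
  exactly to 1/σ_yj².
* **IVW**: weighted least squares of Γ̂ on γ̂ through the origin, weights
  w_j = 1/σ_yj²; θ̂ = Σw γ̂ Γ̂ / Σw γ̂². Heterogeneity: Cochran's
  Q = Σ w_j (Γ̂_j − θ̂ γ̂_j)² on df = J−1 and I² = max(0, (Q−df)/Q)·100.
  "Random effects" is the multiplicative model: SE inflated by
  max(1, √(Q/df)). The additive random-effects variant is not implemented.
* **Weighted median**: the interpolated weighted 50th percentile of the
  sorted Wald ratios with delta-method inverse-variance weights
  (|γ̂_j|/σ_yj)²; consistent when valid instruments carry ≥ 50% of the
  weight. Its SE has no closed form; we use a parametric bootstrap (default
  1000 replicates; explicit seed mandatory) redrawing both γ̂ and Γ̂ from
  normals centred on the observed values.
* **MR-Egger**: WLS of Γ̂ on γ̂ *with* intercept, same weights. The slope is
  a pleiotropy-corrected causal estimate under the InSIDE assumption
  (instrument strength independent of direct effects); the intercept
  estimates the average directional pleiotropy, its p-value the standard
  pleiotropy test. Requires orientation to non-negative exposure betas,
  enforced with a hard error. SEs use the same multiplicative inflation on
  df = J−2.
* **Multivariable MR**: no-intercept WLS of Γ̂ on the J×K matrix of exposure
  betas, weights 1/σ_yj²; coefficient k is exposure k's direct effect
  conditional on the others. Residual Q on df = J−K drives the multiplicative
  SE inflation. A co-exposure whose betas are all exactly zero is excluded
  from the design (direct effect fixed at 0) instead of making the system
  singular; any other rank deficiency is a hard error with the condition
  number reported. Uncertainty in the exposure betas is ignored in the
  weights, as in standard MVMR-IVW; conditional F statistics are out of
  scope.

All confidence intervals and p-values use normal quantiles (1.96 for 95%),
the convention for MR with hundreds of instruments; a t-based alternative was
considered and rejected as needless complexity at these instrument counts.

## Instrument selection and strength

Instruments are SNPs with exposure p < 5×10⁻⁸, pruned by greedy LD clumping:
repeatedly take the most significant remaining SNP (ties by rsid, making the
algorithm deterministic) and remove same-chromosome SNPs within the window
(default 10,000 kb) with r² ≥ the threshold (default 0.01) — retained pairs
therefore satisfy r² < 0.01, the usual definition of independence. The r²
boundary case falls on the removal side. LD comes from a user-supplied
matrix; pairs absent from it are treated as unlinked with a warning
(fail-soft for partial panels) rather than dropped. Without any LD matrix,
window-only pruning is applied.

Strength diagnostics: per-SNP F_j = (γ̂_j/σ_xj)², per-SNP variance explained
F_j/(F_j + n − 2) summed to an approximate R², and the K-instrument score
F = R²(n−K−1)/(K(1−R²)). The frequency-based alternative 2f(1−f)γ̂² for
per-SNP variance is documented but not used for F, since it needs allele
frequencies the outcome GWAS may not report.

## Harmonisation

Matching is by rsID only (published instrument lists are rsID-keyed);
positions feed clump windows, never matching. Outcome alleles equal to the
exposure's are kept; swapped alleles negate the outcome beta and reflect its
frequency; any other configuration is dropped as a mismatch (no strand
inference from reference panels, no proxy SNP lookup). Palindromic SNPs
(A/T, C/G) are resolved by allele frequency under the default
`infer_by_frequency` policy — dropped when either side's frequency lies in
0.5 ± 0.08 (the conventional ambiguity band), sign-corrected when the two
frequencies disagree about the common allele — or dropped wholesale under
`drop_all`. Indel alleles are compared as case-insensitive strings and are
never treated as palindromic. Every drop is logged with a reason, and
retained + dropped always account for the full exposure instrument list.

## Synthetic data generator

The generator emulates the two-sample design directly at the summary level —
no individual-level genotypes — because that is all the estimators consume
and it makes desk-scale Monte Carlo cheap. Per SNP: effect-allele frequency
f_j ~ U(maf_range); true effects γ_j drawn (normal by default) and rescaled
so Σ 2f_j(1−f_j)γ_j² equals `target_R2` exactly; observed betas normal
around the truth with se = 1/√(2f(1−f)n); outcome truth Γ_j = θγ_j + α_j.
A fraction `prop_invalid` of instruments receives α_j ~ N(alpha_mean,
alpha_sd²) — `balanced` forces mean zero, `directional` uses `alpha_mean`.
`overlap_corr` correlates the exposure and outcome sampling errors, a
summary-level stand-in for overlapping GWAS samples; with weak instruments
and a null θ it reproduces the expected drift of IVW toward the confounded
direction.

Allele convention: after drawing, each SNP is canonicalised so the reported
effect allele is the exposure-increasing one (γ_j ≥ 0, frequency flipped).
This is the scale on which "directional" pleiotropy is meaningful — without
it, the orientation step every Egger analysis applies would re-randomise the
signs of α and the intercept test could never have power. Simulated alleles
are non-palindromic and instruments are in linkage equilibrium (clumping is
exercised on hand-built LD fixtures instead).

`simulate_with_mediator` adds pathways exposure → mediator (δ_j = m_x γ_j)
→ outcome (+ m_y δ_j), and gives each mediator its own independent
instruments (default 100 SNPs, 2% variance): with only the exposure's
instruments the mediator betas are exactly proportional to the exposure's
and the multivariable direct effect is unidentified. Whether the co-exposure's
own instruments join the MVMR instrument set is the analyst's choice; the
study pipeline defaults to the primary exposure's instruments only, while
the mediation validation uses the union.

Defaults mirror a large insomnia-style study: preset `insomnia-like` has
J = 208 instruments explaining 2.6% of liability variance in a 1,331,010-
sample exposure GWAS against a 367,586-sample outcome GWAS; `small-fast`
(J = 50, n = 100k/50k) is for quick iteration.

What the generator does *not* emulate: logistic-model non-collapsibility
(the exposure is a continuous liability; θ is interpreted per unit log-odds),
LD between instruments, allele-frequency–dependent effect-size architecture,
population stratification, and winner's curse in instrument discovery.
Passing recovery tests therefore demonstrate the estimators' correctness
under the linear pathway model, not robustness to those real-data features.

## Study pipeline

`run_study` runs, per outcome: instrument selection → harmonisation →
orientation → random-effects IVW (headline) + weighted median + MR-Egger →
odds-ratio transform → evidence tier, plus optional MVMR with one adjustment
trait per model (separate pairwise models, mirroring how such studies report
adjusted analyses; a jointly adjusted model is a one-line change but not the
default). Tiers: `significant` if p < α/m (Bonferroni over the m outcomes,
0.05/9 ≈ 0.006 for a nine-outcome panel), `suggestive` if p < 0.05,
else `limited`. Outcomes with fewer than 3 harmonised SNPs keep their IVW
row but skip median/Egger with a logged warning; a missing outcome file
skips that outcome and flags the run as partially failed. Pleiotropy
flagging uses Egger intercept p < 0.05, exposed as a result column rather
than a hidden rule. Output is a forest-style TSV (outcome × method with OR,
95% CI, p, Q, I², tier), per-outcome SNP tables, drop logs and a resolved
config copy; runs are byte-reproducible given config + seed.

## Numerical choices and validation scale

Estimator linear algebra is explicit (normal equations / `lstsq` on
√w-scaled designs); agreement with independent WLS fits is tested to 1e-10.
Genome-wide filtering uses strict inequality (p < 5×10⁻⁸). The weighted
median interpolates; below the first (above the last) cumulative-weight
midpoint it clamps to the extreme ratio. Monte Carlo validation uses 200
replicates for recovery/robustness means, 1000 for the Egger type-I rate,
and 100 for the mediation contrast — sizes at which the Monte Carlo error is
comfortably below the tolerances being asserted while the whole battery
stays desk-scale (about a minute).

## Known limitations

* No MR-PRESSO, mode-based, Steiger, radial or leave-one-out methods.
* No proxy-SNP substitution, genome-build liftover or VCF parsing.
* LD matrices are consumed, never computed from reference panels.
* The bootstrap SE of the weighted median assumes independent instruments.
* Per-SNP variance explained uses the F-based approximation, which is
  slightly anticonservative for very strong single SNPs.
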