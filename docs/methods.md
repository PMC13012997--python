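# Methods

This note documents the statistical models implemented in `mrlink`, the
defaults and why, what the synthetic-data generators do and do not emulate,
and the numerical choices that were genuinely open.

## Two-sample MR model

Each instrument j carries an estimated effect γ̂ⱼ on the exposure (SE σ_xⱼ)
and Γ̂ⱼ on the outcome (SE σ_yⱼ), from non-overlapping samples, harmonized
to a common effect allele. Under the instrumental-variable assumptions
(relevance, independence, exclusion), Γⱼ = θγⱼ and every Wald ratio
Γ̂ⱼ/γ̂ⱼ estimates the causal effect θ (log-odds per unit liability for
binary traits).

* **IVW**: θ̂ = Σwⱼγ̂ⱼΓ̂ⱼ/Σwⱼγ̂ⱼ², wⱼ = 1/σ_yⱼ² (first-order weights;
  exposure effects treated as fixed). Fixed-effects SE (Σwⱼγ̂ⱼ²)^(−1/2);
  the default random-effects mode multiplies it by √max(1, Q/(k−1)). The
  floor at 1 prevents anti-conservative SEs when the data are
  under-dispersed.
* **MR-Egger**: weighted regression of Γ̂ on γ̂ with intercept, exposure
  effects oriented positive first. The intercept estimates the mean
  directional pleiotropic effect per instrument (InSIDE assumption); SEs
  are scaled by √max(1, RSS_w/(k−2)) and inference uses t with k−2 df.
* **dIVW**: replaces the IVW denominator with Σ(γ̂ⱼ²−σ_xⱼ²)wⱼ, removing
  the weak-instrument attenuation E[γ̂²] = γ² + σ_x². No closed-form SE is
  committed to; a seeded nonparametric bootstrap over instruments (default
  2000 resamples) supplies it, with the standard k/(k−1) correction for
  the plug-in bias of the bootstrap variance. Resamples whose debiased
  denominator is nonpositive are discarded.
* **RAPS**: θ̂ maximizes −½Σ(Γ̂ⱼ−θγ̂ⱼ)²/(σ_yⱼ²+θ²σ_xⱼ²) by bounded 1-D
  optimization started at the IVW estimate; the SE comes from the
  numerical curvature at the optimum. The overdispersion variant adds
  τ² ≥ 0 to every denominator and profiles (θ, τ²) jointly under the full
  Gaussian log-likelihood — the log-variance terms are required there,
  because without them the quadratic objective is maximized by τ² → ∞.
  Robust (Huber/Tukey) loss variants are not implemented.
* **Wald ratio** (single SNP): first-order SE |σ_y/γ̂| by default; the
  second-order form adding Γ̂²σ_x²/γ̂⁴ under the root is available by flag.

Sensitivity: Cochran's Q over per-SNP ratios with weights γ̂ⱼ²/σ_yⱼ²
(df = k−1); leave-one-out re-estimation with sign/significance flags; the
Steiger directionality test comparing instrument-explained variance across
traits, both as a set-level summary (r² = ΣFⱼ/(Fⱼ+n−2), Fisher-z one-sided
p) and as a per-SNP screen used during bidirectional analysis. A
liability-scale correction for binary traits is not applied; the r²
comparison is used only ordinally.

## Multivariable IVW

Direct effects of p exposures from k > p shared instruments:
θ̂ = (BᵀWB)⁻¹BᵀWΓ̂ with W = diag(1/σ_y²), SEs from (BᵀWB)⁻¹ scaled by
max(1, Q_mv/(k−p)). Instrument pooling across exposures defaults to the
strict intersection of available SNPs (conservative); a union mode imputes
absent exposure effects as zero. Instrument strength is reported as the
mean marginal per-SNP F per exposure, labelled `mean_marginal_f` — the
conditional Sanderson–Windmeijer F is deliberately not implemented, and
output never claims it.

## Colocalization

Wakefield's approximate Bayes factor per variant,
labf = ½[ln(σ²/(σ²+W)) + z²W/(σ²+W)], with prior effect SD √W = 0.15 for
quantitative traits and 0.2 for case-control (log-odds) traits — the
conventional defaults, exposed in config. Hypothesis sums H0–H4 are
assembled in log space; the H3 cross-sum uses
(Σe^l1)(Σe^l2) − Σe^(l1+l2) via log-sum-exp and log1p. Priors
p1 = p2 = 10⁻⁴, p12 = 10⁻⁵. Classification: PP.H4 > 0.8 → shared causal
variant; else PP.H3+PP.H4 ≥ 0.8 → shared-or-linked; else unresolved.
Note the ABF is not invariant to rescaling β and SE alone (the shrinkage
ratio depends on the absolute SE scale); the unit-change invariance that
does hold — rescaling β, SE and the prior SD together — is what the test
suite asserts. Inputs are analysed on the beta/SE scale directly; the
MAF-based ABF variant and multi-causal (SuSiE-style) colocalization are
out of scope.

## SMR and HEIDI

SMR: b̂_xy = Γ̂/γ̂ at the top cis-QTL SNP,
T_SMR = z_qtl²z_gwas²/(z_qtl²+z_gwas²) ~ χ²(1), with a top-SNP F ≥ 10
guard. HEIDI: for eligible non-top SNPs (QTL χ² > 10, i.e. p < 1.57×10⁻³;
0.05 ≤ r²(top) ≤ 0.9; the 20 most significant — the conventions of the
original method, recorded as assumptions in output), dᵢ = b̂_xy(i) −
b̂_xy(top) gets a delta-method covariance using LD correlations (QTL and
GWAS samples independent), and T = Σ(dᵢ/sdᵢ)² is referred to a seeded
Monte-Carlo null of the implied mixture of correlated χ²₁ draws (default
10,000; a Satterthwaite approximation was rejected in favour of exact
reproducibility under seeding). Fewer than 3 eligible SNPs yields a
missing HEIDI p with a reason, and such probes never receive `passes=True`
in the screen. Screens convert SMR p-values to BH q-values across probes;
`passes` requires p_HEIDI > 0.05 and q < 0.05. Cis windows default to
1 Mb. The binary BESD format of the original tool is not read.

## LD score regression (simplified)

E[z²] = 1 + N·h²·ℓ/M motivates regressing z² on N·ℓ/M (slope h²,
intercept ≈ 1 absent confounding); E[z₁z₂] = √(N₁N₂)·gencov·ℓ/M + overlap
gives the genetic covariance, and rg = gencov/√(h₁²h₂²). Weights are a
one-step heteroskedasticity scheme fixed from an initial unweighted pass:
1/(1+N·ĥ²·ℓ/M)² per trait for the z² regressions, and the product of the
unsquared per-trait factors for the cross regression (matching
Var(z₁z₂) ≈ (1+a₁)(1+a₂) under near-independence). SEs come from a
delete-one-block jackknife (200 contiguous blocks in genome order) re-run
through all three regressions per block with the weights held fixed — a
simplification of the reference two-step estimator, labelled
`simplified-LDSC` in all output. Constant LD scores are a degenerate
design and raise an estimation error.

## Mediation and PheWAS

Two-step mediation: a (exposure→mediator) and the total effect c use the
exposure's genome-wide-significant instruments; b (mediator→outcome) uses
the mediator's; indirect = a·b with Sobel SE √(a²se_b²+b²se_a²);
direct = c − a·b (so indirect + direct = c identically); proportion = a·b/c,
reported as-is even outside [0,1], with a delta-method CI assuming zero
covariance between the total and indirect estimates — the covariance is
not estimable from separate summary fits, and output flags the CI method.
b defaults to univariable IVW; an MVMR-conditioned b (adjusting for the
exposure) is available by flag. The PheWAS screen clumps cis instruments
at the looser r² < 0.1 / 10,000 kb convention, runs Wald/IVW per outcome,
and applies BH FDR across the estimable outcomes only (outcomes with no
overlapping SNPs are reported but excluded from the FDR denominator).

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (config, seed).

* **Two-sample pairs**: γⱼ ~ N(0, 0.05²), β̂_x = γ + e_x,
  β̂_y = θγ + α + e_y, with e ~ N(0, se²) and
  se = 1/√(2n·eaf·(1−eaf)) — the continuous-trait convention; binary
  log-odds effects are emulated by supplying the same SE form rather than
  committing to a liability model. Defaults n = 100,000 and k = 50 match
  the well-powered regime the estimator checks assume. Directional
  pleiotropy is drawn relative to the exposure-increasing allele (the
  orientation MR-Egger fits under), making its mean identifiable as the
  Egger intercept. Variants are deliberately common, non-palindromic and
  spaced beyond the clumping window so default QC is a no-op on clean
  panels.
* **Regions**: z ~ MVN(Rλ, R) under AR(1) LD (ρ = 0.9 default), causal
  indices placed per colocalization hypothesis H0–H4; cis regions scale
  betas by 1/√n (n = 10,000) so the coloc effect prior sees realistic
  units while SMR/HEIDI, being z-based, are unaffected.
* **LDSC inputs**: per-SNP (z₁, z₂) bivariate normal with
  Var = 1 + N·h²·ℓ/M and Cov = √(N₁N₂)·rg·√(h₁²h₂²)·ℓ/M (+ an optional
  sample-overlap constant), ℓ ~ 1 + Gamma(2, 20), M = 20,000 by default —
  the moment structure the regression assumes, not a forward simulation
  from genotypes.
* **Mediation chains**: two disjoint instrument panels wired so the
  exposure's instruments carry slope a onto the mediator and
  direct + a·b onto the outcome, while the mediator's instruments carry
  slope b onto the outcome and nothing onto the exposure. Sample sizes
  (200k/30k/200k) and effect scales are chosen so each trait's
  genome-wide-significant set is, with high probability, exactly its own
  panel; the residual chance of an exposure instrument crossing the
  mediator threshold (a few percent per chain) is the realistic leakage
  the pipeline must tolerate.

Because the generators draw estimation noise directly at the
summary-statistic level, passing tests demonstrate the estimators'
correctness under their assumed moment structure — they do not probe
finite-LD-panel artefacts, allele-frequency-dependent architectures,
sample overlap between exposure and outcome GWAS (except where planted for
the LDSC intercept), population stratification, or selection-induced
winner's curse in instrument discovery. Real-data work should treat those
as open risks.

## Numerical choices

* Clumping ties on p are broken by (chrom, pos, snp_id) for determinism;
  LD entries missing within the window count as r² = 1 (blocking
  co-selection) and cross-chromosome pairs as r² = 0; `ld=None` means
  independence and is intended for pre-pruned or simulated panels.
* Palindromic SNPs in MR harmonization are kept only when both allele
  frequencies are outside 0.5 ± 0.08 and agree in side; the LDSC path
  drops all palindromes during QC instead. The 0.08 window is exposed in
  config.
* HEIDI's correlation matrix is ridge-repaired (1e-6 on the diagonal) if
  numerically indefinite; eigenvalues are clipped at zero before the
  Monte-Carlo null.
* RAPS curvature uses a central second difference with step
  1e-5·(1+|θ̂|); a nonnegative curvature raises an estimation error rather
  than returning a fabricated SE.
* The proportion-mediated SE is computed in factored form to avoid
  overflow when the total effect is near zero; a zero total reports a
  missing proportion.
* Per-stage pipeline seeds derive as master seed + stage index, so adding
  a stage never shifts another stage's stream.

## Problem sizes

The test suite and acceptance script run the estimator checks at the sizes
stated above (500 replicates for recovery rates, 1000 for size, 200–300
for scenario rates, M = 20,000 SNPs for LDSC), which complete in well
under a minute on one CPU; the unit tests use smaller panels where a
property does not depend on scale.

## Known limitations

CML-MA and BWMR estimators, correlated-instrument (generalized) IVW,
MVMR-Egger/median, SuSiE colocalization, multi-SNP SMR, partitioned LDSC,
genotype-level simulation and multi-mediator decomposition are out of
scope. Instrument adjustment for covariates (e.g. BMI-adjusted discovery)
is not modelled; instrument lists are taken as given or simulated.
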