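# Methods

This note records the statistical models implemented in `targetmr`, the
defaults and why they were chosen, what the simulator does and does not
emulate, and the numerical and design decisions a maintainer would want
to know.

## Causal model and estimators

The pipeline is two-sample summary-data MR. A SNP G is a valid
instrument for exposure X (protein abundance or gene expression, in SD
units) on outcome Y (disease liability on the log-odds scale, or a
quantitative endophenotype) when it is associated with X, affects Y only
through X, and is independent of confounders. Under that model the
marginal effects satisfy β_GY = θ·β_GX, so

- **Wald ratio** (one instrument): θ̂ = β_GY/β_GX,
  SE(θ̂) = SE_GY/|β_GX| (first-order delta method; the second-order term
  is negligible at the F ≥ 10 instrument strength the pipeline
  enforces).
- **IVW** (k ≥ 2 instruments): fixed-effect inverse-variance mean of
  the per-SNP ratios, equivalently the zero-intercept weighted
  regression of β_GY on β_GX with weights 1/SE²_GY. Fixed rather than
  multiplicative random effects because cis instrument counts are tiny
  (1–5 per gene after clumping at r² < 0.001); a heterogeneity model
  has nothing to estimate from.
- **MR-Egger intercept**: the same regression with a free intercept and
  exposure betas oriented non-negative. It is used strictly as a
  directional-pleiotropy diagnostic (flag at p < 0.05), never as the
  reported estimator, and a flagged gene is not dropped — only
  annotated. Its SE uses the usual weighted-regression scale
  (weighted RSS/(k−2)); p-values are two-sided normal.
- 95% CIs use the normal multiplier 1.9600 throughout; ORs are
  exp-transformed log-odds effects.

### Instrument selection

Filter order: cis window + significance → LD clumping → harmonisation →
Steiger → outcome-association exclusion → F-statistic. Defaults:
window ±1,000 kb around the gene body (inclusive at both edges),
P < 5×10⁻⁸ (strict), clump r² = 0.001 within 10,000 kb, outcome
exclusion at P < 5×10⁻⁵ (strict), F ≥ 10. Clumping is the greedy
PLINK-style procedure (most significant unclaimed SNP claims everything
within the distance window at r² ≥ threshold); p-value ties break
lexicographically by SNP id so the output is independent of input
order. The window anchors on the gene start/end rather than the TSS,
which covers both anchoring conventions.

Steiger filtering retains a SNP when its explained-variance proxy in
the exposure is at least that in the outcome, using
r² = z²/(z² + n − 2) for both trait types (monotone in |z| at fixed n;
ties retained). The allele-frequency proxy 2·MAF·(1−MAF)·β² is
available behind `steiger_formula="af"`.

Harmonisation re-orients the outcome record onto the exposure's effect
allele (sign flip and eaf → 1−eaf for reversed pairs). Palindromic A/T
and C/G SNPs are dropped by default because strand cannot be resolved
from two summary files; this is configurable. The 0.2
allele-frequency-difference filter is applied in the SMR stage by
default (where minor-allele and AF-difference checks are standard) and
is available to the MR stage via `af_diff_threshold`. Indels and
multi-allelic records are rejected at parse time; only biallelic SNPs
are analysed.

### SMR and HEIDI

SMR: b_SMR = β_GWAS/β_eQTL with T_SMR = z²_G·z²_E/(z²_G + z²_E)
referred to χ²(1); se_SMR = |b_SMR|/√T_SMR. The χ²(1) reference is
first-order and becomes exact as the eQTL z grows; the test suite
verifies it against a 10⁶-draw Monte-Carlo null at z_eQTL = 20.

HEIDI: SNPs with r² to the top eQTL strictly inside (0.05, 0.9) and
eQTL p < 1.57×10⁻³ (the χ²(1) = 10 equivalent) are eligible, capped at
the 20 most significant; fewer than 3 → not evaluable. The differences
d_i = b_SMR(i) − b_SMR(top) get their covariance from the LD matrix and
per-SNP SEs by the delta method (GWAS and eQTL samples independent),
and Σ(d_i/sd_i)² is calibrated by Satterthwaite moment matching on the
eigenvalues of the d-correlation matrix rather than a saddlepoint
approximation — simpler, and the null simulations below show the
false-call rate at the 0.01 threshold stays below ~2%. Two thresholds
coexist deliberately: 1.57×10⁻³ is per-SNP eligibility, 0.01 is the
pleiotropy/linkage call; both are configurable. A gene whose HEIDI is
not evaluable (insufficient SNPs) is *not* treated as failing the SMR
criterion in tiering, since absence of a linkage test is not evidence
of linkage; `missing_heidi_passes=False` flips this.

### Colocalisation

Wakefield log-ABFs per SNP, single causal variant per trait, hypothesis
sums in log space (log-sum-exp; the H₃ term S₁S₂ − S₁₂ uses log1p of
the negative exponent gap, which is exact because S₁₂ ≤ S₁·S₂ with
equality only for a one-SNP locus). Priors p₁ = p₂ = 10⁻⁴,
p₁₂ = 10⁻⁵; call threshold PPH₄ > 0.7. The per-trait effect-size prior
SDs are not identified by those priors and default to 0.15 (SD-scale
quantitative traits) and 0.20 (log-OR case-control traits), the
conventional values for these scales; both are configurable per trait.
The coloc locus is the full ±1,000 kb cis window without p-value
filtering, since ABF sums need the complete local SNP set.

### Tiering, endophenotypes, PheWAS

Tier classification takes FDR-significant protein MR as the entry gate,
then criterion B (SMR p < 0.05, direction consistent with the protein
effect, no HEIDI call) and criterion C (PPH₄ > 0.7): tier 1 = B∧C,
tier 2 = exactly one, tier 3 = neither; a direction-inconsistent
significant SMR excludes the gene. Missing SMR or coloc evidence makes
that criterion false with an explicit reason (e.g. "no available gene
expression data"). Endophenotype MR reuses the full instrument pass and
reports betas with raw p at 0.05 (continuous outcomes, no OR scale).
The PheWAS scan keeps phenotypes with strictly more than 500 cases and
adjusts BH-FDR across the scanned set per target. Replication across
cohorts is summarised as a direction-concordance report, not a
meta-analysis.

## The simulator

Summary statistics are drawn from the RSS multivariate-normal model for
marginal z-scores: z ~ MVN(√(n·v̄)·R·β_joint, R) with R the locus LD
matrix (AR(1) or block), β_joint the causal effects on the standardised
scale, and v̄ = 1 for quantitative traits or φ(1−φ) for a binary trait
with case fraction φ (log-OR scale with effective-n SE = 1/√(n·v̄)).
Exposure and outcome draws use independent noise, matching the
two-sample design. Architectures: shared (b_out = θ·b_exp), distinct
(outcome has its own causal variants), pleiotropy (θ·b_exp plus direct
SNP effects), reverse (outcome causal, b_exp = φ_rev·b_out).

Defaults mirror the data conditions the pipeline is designed for: a
35,559-sample plasma pQTL panel, a 31,864-sample blood eQTL panel, a
binary disease outcome of effective size 139,900 at case fraction
0.147, a 200-SNP AR(1) ρ = 0.95 locus with MAF uniform on (0.05, 0.5),
5 kb SNP spacing, and a cis causal effect of 0.15 SD per allele — a
strong cis-QTL, which is exactly the instrument regime the method
presumes. Recovery and discrimination studies use n = 50,000 per trait,
large enough that asymptotic calibration is the question being tested
rather than small-sample noise.

What the simulator does **not** emulate: genotype-level sampling (no
winner's-curse interplay between overlapping samples), rare variants,
indels and strand ambiguity (simulated panels are biallelic and
non-palindromic by construction), population structure, multi-ancestry
LD, and LD-reference mismatch (the analysis sees the true R). Passing
tests therefore demonstrate internal correctness and calibration under
the stated model, not robustness to those real-data pathologies.

## Numerical choices

- p-values from z-scores are clipped below at 10⁻³²⁰ to stay in (0, 1];
  the parser's beta/SE-vs-p consistency check (10% relative tolerance)
  skips tails below 5×10⁻³⁰⁰.
- Near-singular LD (|ρ| → 1) gets a 10⁻⁸ diagonal jitter before
  Cholesky, with a logged note; Cholesky factors are cached per LD
  specification.
- Summary-statistic and LD files are written at %.17g so read→write
  round-trips are bit-identical (`float_precision="round_trip"` on the
  read side).
- HEIDI drops covariance eigenvalues below 10⁻¹² (numerically null
  directions from near-perfect LD).
- Clump and top-eQTL ties break on (p, snp_id); all such orderings are
  deterministic.

## Calibration studies and problem sizes

`targetmr.validation` (exercised by `tests/test_acceptance.py` and
`scripts/acceptance.py`) runs: Wald/IVW coverage and type-I error at
θ ∈ {−0.3, 0, 0.3} over 500 replicate loci each; coloc discrimination
over 200 shared and 200 distinct-variant loci (distinct variants placed
~100 SNPs apart, r² < 0.1); HEIDI false-call rate over 500 shared-variant
loci and power over 200 distinct-variant loci at r ≈ 0.6 (10 SNPs apart
under ρ = 0.95); and 50 null PheWAS scans of 783 phenotypes each. The
recovery studies disable the outcome-association exclusion filter: with
a strong true effect the instrument is genuinely outcome-associated at
P < 5×10⁻⁵, and the filter — designed to remove instruments acting
through pathways other than a (weak-effect) exposure — would delete
every valid instrument. That interaction is a property of the filter
worth knowing when true effects are large; the filter remains on by
default in the pipeline itself.

## Known limitations

- Single-causal-variant coloc (no conditioning or SuSiE-style
  extension); multi-signal loci will dilute PPH₄.
- HEIDI's delta-method/Satterthwaite calibration degrades when eligible
  SNPs have weak eQTL signals (ratio bias); the eligibility threshold
  exists to bound this, but extremely small eQTL panels are outside the
  validated regime.
- The Egger diagnostic has low power at the 1–5 instrument counts
  typical of cis-only analyses; it is reported, not relied on.
- Binary-trait simulation is on the log-OR scale with effective-n SE
  scaling, not a liability-threshold genotype model; absolute-risk
  quantities are out of scope.
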