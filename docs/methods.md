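# Methods

## Model and assumptions

The package estimates the effect of a gene's expression (exposure *x*) on a
disease outcome *y* from two independent sets of summary statistics, using
cis-eQTL variants as instruments. The instrumental-variable assumptions are
the usual ones: relevance (enforced by the eQTL p and F filters), independence
(inherited from the GWAS designs) and exclusion restriction (probed, not
guaranteed, by HEIDI, colocalization and the cis-pleiotropy scan). All
estimators operate on marginal per-allele effects and treat the supplied LD
correlation matrix as known; sampling error in LD is not modelled.

Effect scales follow the sources: eQTL betas are SD of expression per effect
allele, case-control outcome betas are log odds per allele, so Wald ratios are
log odds per SD of expression. Odds ratios are reported per SD *decrease*
when the drug inhibits its target.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| cis flank | 1,000,000 bp | cis window on either side of the gene body |
| eQTL p | 5e-8 | instrument significance threshold |
| MAF | > 0.01 | common-variant filter, `min(eaf, 1-eaf)` |
| F | > 10 | weak-instrument screen, single-SNP F = (β/se)² |
| validation p | 0.05 | SMR p gate against the blood-pressure GWAS |
| HEIDI p | 0.01 | below this, the signal is attributed to linkage |
| HEIDI candidate eQTL p | 1.6e-3 | cis SNPs eligible for the heterogeneity test |
| HEIDI r² band | [0.05, 0.9] | LD with the top SNP; 3–20 SNPs used |
| multi-SNP prune r² | 0.1 | pairwise cap in the multi-SNP SMR set |
| coloc priors | 1e-4, 1e-4, 1e-5 | per-SNP causality priors p1, p2, p12 |
| coloc effect priors | 0.15·sdY / 0.2 | Wakefield prior SD, quantitative / log-odds |
| PP4 support | 0.80 | conventional colocalization support level |
| pleiotropy window | 2,000,000 bp | nearby-gene scan around the top SNP |
| GSMR selection / prune | 5e-8 / r² 0.05 | exposure instrument set |

The HEIDI candidate threshold (1.6e-3) and the GSMR thresholds are the
standard defaults of the tools that introduced those tests; the validation and
HEIDI gates are the analysis's own conventions. All are exposed as
`AnalysisConfig` fields and CLI flags.

## Numerical choices

- **Weighted chi-square tails.** Both HEIDI and multi-SNP SMR refer a sum of
  squared correlated normals to `Σ λ_k χ²₁`. The tail probability is computed
  by Imhof's exact characteristic-function inversion (adaptive quadrature),
  with two closed-form short-circuits: a single surviving weight and an
  equal-weight set are exact scaled chi-squares. Below p = 1e-10 the
  quadrature loses precision and the two-moment Satterthwaite value is used —
  at that depth the decision (reject at 0.01) is unaffected. Satterthwaite is
  also available as `method="satterthwaite"`; its absolute error against a
  100,000-draw Monte-Carlo oracle reaches ~0.015 in the mid-range, which is
  why it is not the default.
- **Ratio covariances.** HEIDI and GSMR use the first-order delta method for
  Var(β_gy/β_gx) and its LD-induced covariances; terms of order se_gx⁴ are
  dropped. This is accurate when instruments pass the F > 10 screen.
- **Near-singular HEIDI covariance.** If the difference-vector correlation
  matrix is rank-deficient (SNPs in near-perfect LD), the SNP most collinear
  with the rest is dropped iteratively before inversion.
- **Ties.** Top-SNP selection breaks eQTL-p ties by larger F, then
  lexicographic rsid; outlier removal breaks underflowed-p ties by larger |z|.
  Both make pipelines deterministic.
- **Log-space coloc.** All Bayes-factor sums use log-sum-exp; per-SNP ABFs
  overflow doubles at |z| ≳ 40 otherwise. The H3 pair sum is computed as
  `exp(lse1 + lse2) − exp(lse12)` in log space, which is exactly the ordered
  i≠j sum.
- **Palindromic variants.** A/T and C/G variants cannot be strand-oriented
  from allele labels; they are oriented by minor-allele concordance and
  dropped when either study's EAF is in [0.42, 0.58].
- **Degenerate inputs.** β_gx = 0 is a hard error for ratios; a zero GWAS
  z gives T_SMR = 0, p = 1 and an infinite ratio SE (OR CI reported as
  (0, ∞) rather than failing).

## The synthetic generator

`simulate_pair` draws marginal z-scores directly: `z ~ MVN(Λζ, Λ)` where Λ is
a block-diagonal AR(1) LD matrix and ζ carries the standardized causal
effects, `ζ = β·sqrt(2·maf·(1−maf)·n)` (case-control SEs additionally scaled
by `φ(1−φ)` for case fraction φ). Betas are recovered as `z·se`. The eQTL and
GWAS draws are independent, matching the two-sample design. Defaults emulate
the source studies: n_eqtl = 31,684, n_gwas = 214,675 with case fraction
0.552, causal eQTL effect 0.3 SD per allele (top-eQTL z ≈ 38, the strong end
of the published per-gene range of roughly 4–45), MAF ~ U(0.05, 0.5), one
100-SNP AR(0.8) block.

Three scenario kinds realize the competing hypotheses: `null` (an eQTL with no
outcome effect), `shared_causal` (outcome effect `b_xy_true` mediated through
expression at the same variant) and `linkage` (a distinct outcome variant in
LD with the eQTL).

What the generator does *not* model: individual genotypes, sample overlap
between studies, population structure, winner's-curse bias in instrument
selection, allele-frequency mismatch between studies, or LD estimated with
error. Passing calibration tests on this model therefore demonstrates the
estimators' correctness under their own assumptions, not robustness to those
real-data complications.

## Power of the multi-SNP SMR test

Whether aggregating cis SNPs beats the top-SNP test depends on instrument
strength. With a moderately strong causal eQTL (z ≈ 15), the multi-SNP
statistic is at least as significant as the top-SNP statistic in well over 60%
of shared-causal replicates — the regime the test is designed for, where the
selected top SNP is often not the causal variant. With an overwhelmingly
strong instrument (z ≈ 38) the top SNP essentially is the causal variant and
additional pruned SNPs mostly add null degrees of freedom, so the multi-SNP p
is usually larger. The suite tests the claim in the moderate regime and the
equal-oracle reductions exactly.

## Simulation sizes used in the suite

Type-I calibration of SMR uses 1,000 null regions; effect recovery, HEIDI
discrimination (linkage vs shared) and GSMR null calibration use 200
replicates each; HEIDI-p uniformity uses 500; the weighted-chi-square oracle
uses 20 random 5-SNP configurations against 100,000 Monte-Carlo draws. These
sizes give binomial standard errors comfortably inside the asserted bands.

## Design choices where the design was open

- **Single-SNP F as z².** The standard summary-data approximation; no formula
  is fixed by convention for marginal eQTL rows.
- **Positions 1-based, intervals closed** on both ends, matching rsID-table
  usage.
- **Tissue specificity** is defined as expression ≥ 5× the mean of the other
  tissues — a deliberate simplification standing in for the richer definitions
  of dedicated enrichment packages, combined with the fold ≥ 2 and BH-adjusted
  p < 0.05 significance rule. Treat the enrichment module as a transparent
  surrogate, not a reimplementation of any specific tool.
- **Case-control coloc prior.** The log-odds prior SD 0.2 is used directly;
  no case-count rescaling is applied, matching the standard ABF
  parameterization for binary traits.
- **Top-SNP-table mode.** When the input is a pre-extracted per-gene top-SNP
  table (like the packaged published rows), region-dependent stages (HEIDI,
  multi-SNP SMR, coloc) are reported as "insufficient region data" instead of
  failing, so printed tables are a first-class input.
- **Validation stage** uses top-SNP SMR plus HEIDI by default; whether the
  original analysis used multi-SNP SMR there is not stated, and the choice is
  switchable.

## Known limitations

- Colocalization assumes a single causal variant per trait per region; the
  multi-causal extension is out of scope.
- The published real-data posterior probabilities, gene-count ladder
  (154 → 72 → 32 → 23) and tissue list depend on the full eQTLGen/BCAC/GTEx
  and expression-atlas resources and cannot be reproduced from the packaged
  per-gene rows; the packaged tables support worked-example transforms only.
- HEIDI requires an explicit LD matrix; none is inferred from summary data.
- Egger regression uses exposure-beta sign orientation and weights 1/se_gy²;
  no correction for regression dilution (NOME violation) is applied.
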