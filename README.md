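# drugtarget-mr

Two-sample summary-data Mendelian randomization (MR) of drug-target gene
expression on disease risk, built for the question: *does long-term
pharmacological modulation of a target gene's expression change disease risk?*
The motivating application is antihypertensive drug targets and breast cancer:
cis-eQTL instruments for each target gene's whole-blood expression are
validated against a systolic-blood-pressure GWAS, then tested against breast
cancer GWAS outcomes (overall, ER status, molecular subtypes), with
colocalization, cis-pleiotropy scanning, multi-instrument MR and tissue
enrichment as sensitivity analyses.

It is a library plus a thin `drugtarget-mr` command line, intended for
genetic epidemiologists who have per-variant summary statistics (beta, SE, p,
EAF, N) and regional LD matrices rather than individual-level data.

## The statistics

For instrument *g*, exposure *x* (gene expression) and outcome *y*:

- **Wald ratio** — `β_xy = β_gy / β_gx`, with the delta-method SE
  `sqrt(se_gy²/β_gx² + β_gy²·se_gx²/β_gx⁴)`. For a case-control outcome
  β_xy is the log odds per SD of expression and `exp(−β_xy)` the odds ratio
  per SD *decrease* (the natural direction for an inhibiting drug).
- **SMR test** — `T_SMR = z_gx²·z_gy²/(z_gx²+z_gy²)` referred to χ²(1);
  the multi-SNP extension sums T over an LD-pruned instrument set
  (r² < 0.1, up to 20 SNPs) with the eigenvalue-weighted null
  `Σ λ_k χ²₁`, λ_k from the retained SNPs' LD correlation matrix.
- **HEIDI** — tests whether all cis SNPs in intermediate LD with the top
  eQTL give the same Wald ratio. Differences `d_i = β_xy(i) − β_xy(top)`
  get a delta-method covariance; `Σ z_d,i²` is referred to the weighted
  χ² null via exact Imhof inversion. Small p (< 0.01) indicates linkage of
  two distinct causal variants rather than one shared variant.
- **Colocalization** — Wakefield approximate Bayes factors per SNP
  (`log ABF = ½log(1−r) + ½·r·z²`, r = W/(V+W)) combined into posterior
  probabilities PP0–PP4 over the five sharing hypotheses under priors
  p1 = p2 = 1e-4, p12 = 1e-5; PP4 > 0.8 supports one shared causal variant.
- **GSMR-style multi-instrument MR** — per-SNP Wald ratios pooled by
  generalized least squares with Ω_ij = r_ij·se_i·se_j after iterative
  HEIDI-outlier removal (p < 0.01), alongside IVW and Egger regression.
- **Instrument filters** — cis window of 1 Mb around the gene, MAF > 1%,
  eQTL p < 5e-8, single-SNP F = (β/se)² > 10.
- **Tissue enrichment** — hypergeometric upper-tail test of drug-target
  overlap with tissue-specific gene sets, BH-adjusted, significance called
  at fold ≥ 2 and adjusted p < 0.05.

A synthetic-data module (`drugtarget_mr.synthetic`) draws paired eQTL/GWAS
z-scores from the multivariate-normal model `z ~ MVN(Λζ, Λ)` over block-AR(1)
LD, under null / shared-causal / linkage truths, at the sample sizes of the
emulated sources (31,684 whole-blood eQTL samples; 118,474 cases + 96,201
controls). The printed per-gene top-SNP rows of the source analysis ship as a
typed fixture (`drugtarget_mr.tables.fixture_from_tables`).

## Worked example

Top-SNP MR of *SLC12A2* (NKCC1, the loop-diuretic target) expression on
overall breast cancer risk, from its published top cis-eQTL rs17764730:

```bash
cat exposure.ma
# SNP         A1  A2  freq  b       se     p        N
# rs17764730  T   C   0.21  -0.186  0.009  3.2E-86  31684
cat outcome.ma
# SNP         A1  A2  freq  b       se     p        N
# rs17764730  T   C   0.21  0.028   0.007  7.57E-05 214675

drugtarget-mr smr --eqtl exposure.ma --gwas outcome.ma \
    --top rs17764730 --per-sd-decrease
```

prints

```
b_xy=-0.1505 se=0.0383 p_SMR=8.6e-05 OR=1.16 (95% CI 1.08-1.25)
```

i.e. each SD decrease in *SLC12A2* expression is associated with 16% higher
odds of breast cancer (per-allele effects: the T allele lowers expression by
0.186 SD and raises the log odds by 0.028; their ratio, sign-flipped to the
per-SD-decrease convention and exponentiated, is the OR).

The same numbers are available in the library:

```python
from drugtarget_mr import wald_ratio, smr_test, to_odds_ratio
b_xy, _ = wald_ratio(-0.186, 0.009, 0.028, 0.007)   # -0.1505
_, p, se = smr_test(-0.186, 0.009, 0.028, 0.007)    # p = 8.6e-05
to_odds_ratio(b_xy, se, per_sd_decrease=True)       # (1.16, 1.08, 1.25)
```

End-to-end runs go through a YAML config (`drugtarget-mr run --config cfg.yaml`;
see `drugtarget_mr.pipeline.AnalysisConfig` for the keys), and
`drugtarget-mr simulate` emits synthetic eQTL/GWAS/LD triples in the same flat
dialects for pipeline rehearsal.

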