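# grscore

Genetic risk scores for psoriasis from a fixed panel of replicated
susceptibility SNPs, with the downstream analyses that such a score supports:
discrimination (ROC/AUC with paired DeLong comparison), quartile odds ratios
with the Cochran-Armitage trend test, liability-threshold estimates of the
genetic variance each locus explains, subphenotype and gene–gene interaction
models, and family-level score summaries. A synthetic-data generator with the
same statistical structure makes every stage testable without access to
subject-level genotypes.

## Who this is for

Statistical geneticists and methodologists who want a small, fully tested
reference implementation of the classic polygenic-score workflow for a
common immune-mediated disease (psoriasis, ~2–3% prevalence in Europeans,
dominated by the *HLA-C* locus), either to analyse their own risk-allele
dosage tables or to study the behaviour of the methods on simulated data.

## The scores and models

For subject *j* with risk-allele dosages `d_ij ∈ {0,1,2}` over a panel of
*K* SNPs with per-allele odds ratios `OR_i`:

- **count score** `cGRS_j = Σ_i d_ij`
- **weighted score** `wGRS_j = Σ_i d_ij · ln(OR_i)`

so a homozygous risk genotype at OR 1.59 contributes `2·ln(1.59) ≈ 0.927`
wGRS units. Subjects with any missing genotype are excluded (complete-case
rule), never rescaled or imputed.

Under Hardy–Weinberg equilibrium and between-SNP independence the exact
probability law of either score follows by 3^K enumeration, giving analytic
population means (`2·Σ q_i·w_i`), analytic AUCs
(`P(S_case > S_control) + ½P(tie)`), and a closed-form check on any
empirical result.

**Variance explained (liability threshold model).** Disease occurs when a
standard-normal latent liability exceeds `T = Φ⁻¹(1−K)` at prevalence
`K = 0.025`. For a SNP with control risk-allele frequency *q* and per-allele
OR, genotype relative risks `(1, OR, OR²)` and prevalence conservation
`Σ f_g·pen_g = K` give genotype penetrances, thresholds
`t_g = Φ⁻¹(1−pen_g)`, liability means `μ_g = T − t_g`, and the variance
explained `Σ f_g μ_g² − (Σ f_g μ_g)²`; panel totals sum over independent
loci.

## Worked example

The ten-SNP psoriasis panel (odds ratios and case/control risk-allele
frequencies for *HLA-C*, *IL12B*, *IL23R*, *LCE3C/3D*, *TNIP1/ANXA6*,
*IL13*, *CDKAL1*, *TNFAIP3*, *IL23A/STAT2*, *ZNF313*) ships with the
package:

```bash
python -c "from grscore import psoriasis_panel; psoriasis_panel().table.to_csv('panel.csv', index=False)"
grscore simulate --panel panel.csv --mode liability --n-case 724 --n-control 1995 \
                 --seed 1 --out-prefix sim
grscore score     --panel panel.csv --genotypes sim_genotypes.tsv --out scores.tsv
grscore roc       --scores scores.tsv --subjects sim_subjects.tsv --compare wgrs,cgrs --out roc.tsv
grscore liability --panel panel.csv --prevalence 0.025 --out variance.tsv
```

prints

```
wrote 2719 case-control subjects
complete-case rule removed 0 subjects
AUC wgrs=0.7123 cgrs=0.6433 p=1.04e-14
total variance explained: 0.1162 (11.6%)
```

The simulated cohort uses a liability model whose per-SNP effects are
calibrated so an additive logistic fit recovers the panel's odds ratios;
at these sample sizes the weighted score separates cases from controls with
AUC ≈ 0.71 and is decisively better than the unweighted count (paired
DeLong p ≈ 10⁻¹⁴), while the whole panel explains 11.6% of the
liability-scale genetic variance at 2.5% prevalence — *HLA-C* alone
accounting for more than half of that. `grscore run --config run.yaml`
chains QC, scoring, association, ROC, liability and family stages into one
reproducible report (TSV tables plus `summary.json`).

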