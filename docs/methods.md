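# Methods

## Scores

Both scores operate on risk-allele dosages `d ∈ {0,1,2}` oriented by the
panel's risk/non-risk allele pair. The weighted score uses natural-log odds
ratios as weights, `wGRS = Σ d_i·ln(OR_i)`; with OR 1.59 a homozygous risk
genotype contributes 2·ln(1.59) = 0.9275. The weights come from the panel's
own `odds_ratio` column (the study-specific adjusted per-allele estimates),
not from external literature values. The count score is the unweighted
dosage sum and equals the weighted score whenever all weights are 1.

Missing genotypes are never imputed: a subject with any missing dosage is
excluded before scoring (complete-case rule). There is no per-subject
rescaling by the number of typed SNPs — with a ten-SNP panel and low
missingness the complete-case rule loses little and avoids scale artifacts.

Quartiles are the 25/50/75 empirical percentiles of the pooled analyzed
sample (cases + controls after complete-case filtering); a score exactly on
a boundary goes to the lower quartile. Pooled boundaries are the only choice
under which "quartile" partitions the analyzed sample; defining them on
controls only is a plausible alternative and changes boundaries slightly,
but not the monotone OR pattern.

## Exact score laws

Under HWE each SNP's dosage is Binomial(2, q); under between-SNP
independence the score law is the K-fold convolution of three-point laws,
enumerated exactly for K ≤ 12 (3^10 = 59049 states for the packaged panel).
Support points equal within 1e-12 are merged — ln(OR) sums are
floating-point, so distinct genotype vectors can produce the same score.
The analytic AUC between two such laws is the Mann-Whitney functional
P(S_case > S_control) + ½P(tie) summed over the product of supports.
Reconstructing the published empirical AUCs this way ignores any HWE
deviation in cases and the sampling correlation of the real data, so
agreement to about one percentage point is the expected fidelity, not a
defect.

## Liability threshold model

Prevalence is fixed at K = 0.025 (psoriasis in Europeans). Genotype
frequencies come from control allele frequencies under HWE — at 2.5%
prevalence controls approximate the population. Genotype relative risks are
multiplicative in the per-allele OR, (1, OR, OR²), and the baseline
penetrance solves prevalence conservation in closed form:
`pen_0 = K/(f_0 + f_1·OR + f_2·OR²)`. The reported quantity is the raw
between-genotype variance of liability means, `Σ f_g μ_g² − (Σ f_g μ_g)²`
with `μ_g = Φ⁻¹(1−K) − Φ⁻¹(1−pen_g)` — not normalised by 1 + that
variance — and panel totals are simple sums over loci (no LD correction;
the panel's SNPs sit on different chromosomes or are treated as
independent). These conventions were chosen because they reproduce the
published per-SNP variance table to the printed precision; the model is
inconsistent (penetrance ≥ 1) only for OR/prevalence combinations far
outside the panel's range, and such inputs raise an error.

## Association statistics

Logistic fits are maximum-likelihood (statsmodels) with Wald odds ratios,
95% CIs `exp(β ± 1.96·SE)` and two-sided p-values. All models accept an
arbitrary covariate matrix; the intended default adjustment is sex plus
four ancestry principal components supplied as `cov_` columns — ancestry
inference itself is out of scope. Perfect separation and non-convergence
are flagged (infinite-CI sentinel), never raised mid-scan.

Subphenotype models are fit in cases only, with the score per wGRS unit by
default and per sample SD as an option; the modelled level of a string
label is the lexically larger one unless named explicitly.

The Cochran-Armitage trend test uses linear column scores 1..k and the
textbook variance; on a 2×2 table it reduces exactly to the two-proportion
z-test. The Mann-Whitney comparison uses exact enumeration when the smaller
sample has ≤ 8 observations and the tie-corrected normal approximation
otherwise. The interaction scan fits a product-term logistic per SNP pair
(dosage_i + dosage_j + dosage_i·dosage_j + adjustments) with Bonferroni
correction over the C(K,2) pairs; the case-only variant drops control rows,
not model terms. The Hardy-Weinberg test is the exact conditional test
(probability of the observed heterozygote count given the allele counts,
summed over all tables no more probable), computed with the stable
mode-outward recurrence; QC computes MAF and HWE in controls only, after
the subject call-rate filter. The HWE threshold is a config value, not a
constant, because reasonable pipelines use different stringencies for study
samples and external control databases.

## ROC and DeLong inference

AUC is always the Mann-Whitney estimator with the ½-tie convention — the
count score is integer-valued, so ties are common and material. Standard
errors and the paired two-score comparison use the DeLong structural
components (per-case and per-control placement values computed via
midranks in O(n log n)); CIs are Wald on the DeLong SE. DeLong is the
standard correlated-AUC comparison in the R ecosystem this workflow
descends from, and the implementation is cross-checked in the test suite
against both a direct component-enumeration oracle and R's pROC. AUCs here
are in-sample; cross-validated discrimination is deliberately out of scope.

## Synthetic data

The generator's defaults are the study conditions: 724 analyzed cases and
1995 analyzed controls, prevalence 2.5%, 281 nuclear families ascertained
for ≥ 1 affected sibling, four null standard-normal covariates, balanced
sex.

*Frequency mode* draws dosages Binomial(2, case_freq) for cases and
Binomial(2, control_freq) for controls — exactly the structure the analytic
laws assume.

*Liability mode* draws genotypes at population (control) frequencies and
assigns disease when `Σ d_i·β_i + ε > T`, ε standard normal. Each β_i is
calibrated by one-dimensional root finding so that the *marginal* additive
logistic per-allele OR equals the panel OR at the configured prevalence,
with the distribution of the other nine SNPs' liability contribution
enumerated exactly (Jacobi sweeps to joint convergence; support compressed
on a 2e-3 grid, far below the calibration tolerance). This makes parameter
recovery a closed loop: fitting the panel's association model to the
synthetic data returns the panel, which the tests verify to ±5% at 10⁵
subjects per class.

*Families* draw parents from the population under HWE, transmit one allele
per parent per SNP by Mendelian segregation, and determine affection with
the same liability model plus a shared within-family residual component
(default variance 0.3, individual residual reduced to keep the marginal
liability standard normal — representing the familial clustering due to the
~88% of genetic variance the panel does not tag). Sibship sizes are drawn
from truncated Poissons targeting the study's mean sibship composition
(2.32 affected + 1.24 unaffected); because affection is generated by the
liability model rather than imposed, the realized affected counts fall
below the targets — real multiplex families cluster far beyond what ten
SNPs explain, and the generator makes no attempt to hide that. Ascertainment
keeps families with at least one affected offspring.

What passing tests on these data do **not** show about real data: the
generator has no LD between SNPs, no HWE deviation in cases beyond that
induced by ascertainment, no genotyping error, no population stratification
with a true effect (the optional covariate shift is null by default), and
family affection clustering driven by a single Gaussian shared effect. The
published quartile ORs, subphenotype ORs and family means depend on the
real genotype correlation structure and are therefore checked only as
qualitative properties (ordering, sign, calibration), never as numbers.

## Numerical choices

- Score-law merging tolerance 1e-12; enumeration limited to 12 SNPs, larger
  panels are directed to simulation.
- Exact HWE p-values match full enumeration to < 1e-12 for totals ≤ 200
  (property-tested).
- Brent root finding for penetrance thresholds and liability calibration
  (xtol 1e-10); calibration sweeps stop at max |Δβ| < 1e-5.
- Wald inference throughout for logistic terms; p-values floored at the
  smallest positive double, CIs exactly `exp(β ± 1.96·SE)`.
- Degenerate inputs fail loudly: constant dosage, one-class labels,
  zero-margin tables, < 4 distinct scores for quartiles, < 3 complete
  family pairs for the correlation.
- All randomness flows through `numpy.random.default_rng(seed)`; a fixed
  seed reproduces every dataset byte-for-byte.

## Problem sizes used in the test suite

Simulation-backed checks use 10⁵ subjects per class for parameter-recovery
and distribution-matching assertions, 2 000 subjects per replicate and 10⁴
replicates for type-I-error calibration of the trend and interaction tests,
and 40 replicates of 180 families for the within-family correlation sign
check — sizes at which the sampling error of each assertion is an order of
magnitude below the tolerance being asserted.

## Known limitations

- Weights are taken from the same data conventionally used to fit the ORs;
  in-sample AUCs are optimistic, and the package deliberately offers no
  cross-validation.
- The liability total assumes independent loci; with LD it overstates the
  joint variance explained.
- VCF ingestion matches alleles by string identity and refuses strand
  flips rather than guessing; with a ten-SNP panel silent strand inference
  is riskier than failing.
- No transmission-based family tests (TDT) and no heritability estimation
  from family resemblance; family data feed only the mean-score summaries.
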