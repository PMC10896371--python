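# Methods

This note documents the models and procedures `demrisk` implements, the
synthetic data-generating process the analyses run on, the numerical and
design choices that were genuinely open, and what the passing tests do and
do not establish about real EHR-linked biobank data.

## The risk-modeling procedure

### Demographic offset

Case status is first regressed on age, sex, and ancestry-specific
principal components with an ordinary logistic model. Its fitted linear
predictor enters every genetic model as a fixed, unpenalized offset:

    logit P(y_i = 1) = β₀ + Σ_j β_j x_ij + offset_i

so the genetic coefficients describe risk beyond demographics and
population structure. A description of this step as "subtracting predicted
values from the outcome" has no valid likelihood for a binary outcome; the
fixed-offset formulation is the coherent reading of the model equation and
is what we implement.

Two details matter:

* **Offsets are refitted inside each cross-validation training fold** when
  the fold-honest path is used (`fit_genetic_model(offset_covariates=...)`,
  the default inside the permutation loop). Fitting the demographic model
  once on the full resample leaks ≈0.07 AUROC of in-sample optimism into
  the pooled hold-out predictions — measurable on data where nothing
  predicts — because the ~8 demographic parameters are estimated on the
  same samples they later score. The fold-honest variant removes this
  optimism entirely; it is a deliberate improvement over refitting once
  per resample.
* **Perfect separation** falls back to a ridge penalty of 1e-6 with a
  warning; constant covariate columns are dropped with a notice.

### Model families

* `apoe` — the APOE-ε4 allele count alone (0/1/2).
* `single_prs` — one standardized PRS (by default the European-ancestry AD
  PRS on the min-P candidate set).
* `multi_prs` — all available (phenotype × candidate-set) PRSs jointly.
* `enet_snp` — individual candidate-SNP dosages under an elastic-net
  penalty, standardized per training split, intercept unpenalized.

The first three are unpenalized maximum-likelihood fits (statsmodels GLM
with offset). The elastic net is solved by an accelerated proximal-gradient
method (FISTA with adaptive restart) written for this package: the
coordinate-descent solver in the general-purpose library did not converge
on correlated candidate pools at the ~5 ms/fit cost the permutation loop
requires, and was retained only as a cross-check oracle in the tests. The
objective is mean negative log-likelihood plus
`α (λ‖β‖₁ + (1−λ)/2 ‖β‖₂²)`; soft-thresholding yields exact zeros.

### Hyperparameters

Defaults: mixing λ ∈ {0.1, 0.5, 0.9} with 20 log-spaced penalty strengths,
chosen by 3-fold inner cross-validation maximizing AUPRC inside each outer
training split (nested, so pooled out-of-fold predictions stay honest).
Inside permutation loops this grid is too expensive; there we use a
one-decade log grid (α ∈ {0.01, 0.022, 0.047, 0.1}, λ = 0.5) sized for
cohorts of a few hundred samples and ~100 features. Support-recovery
analyses at n ≈ 2000, p ≈ 300 use a weaker grid (α ≤ 0.024): the penalty
scale shrinks roughly with √(log p / n), and prediction-optimal penalties
systematically shrink the weakest true effects (0.2 log-odds) out of the
support.

### Evaluation

Controls are resampled without replacement at a 1:3 case:control ratio,
1000 times by default (reduced in the test suite and acceptance analyses
to 25–200 iterations to keep runtimes practical; iteration counts are
printed with every result). Every model family is refitted on the identical
resample. AUPRC is the step-wise precision–recall integral (no
interpolation; interpolated PR curves are biased); AUROC is the
Mann–Whitney statistic with tie correction. The decision threshold for
confusion-matrix metrics maximizes the MCC over all midpoints between
distinct sorted scores, smallest threshold on ties. CIs are 2.5/97.5
percentiles of the permutation draws. Model comparison uses
`P = #{metric₁ ≥ metric₂}/N` on paired iterations, ties counted in the
numerator, with model 1 the comparator hypothesized inferior; a zero count
is reported as `< 1/N`.

Because the case set is fixed and only controls are resampled, the
permutation distribution does not average over case draws: under a null
generating process the median AUROC across iterations is itself a random
variable with spread ≈ the single-sample AUROC standard error
(≈ 0.58/√n_cases). Null-calibration checks therefore need cohorts of
1000+ cases for a ±0.05 band to be a multi-sigma statement.

### Age covariate and a phenotyping artifact

The model's age covariate is onset age for cases and age at last encounter
for controls (configurable). These reference points are structurally
different: onset falls mid-record while controls' last visits are
constrained to ≥70, so age separates cases from controls at AUROC ≈ 0.7
*even when the liability is pure noise*. This is an artifact of the
eligibility design, not a property of the genetics; it is absorbed by the
offset and shared by all model families, so paired comparisons are
unaffected, but absolute metric levels on this covariate scheme cannot be
read as genetic signal. Null-calibration analyses use the symmetric
alternative (last-encounter age for everyone).

## SNP prioritization

Genomic risk loci: among variants with P < 5e-8, seed a locus at the
smallest P and recruit every unassigned significant variant with r² ≥ 0.2
to the seed (r² = squared Pearson dosage correlation in the
ancestry-matched reference subset; cross-chromosome r² ≡ 0); iterate until
all significant variants are assigned. P ties break by (chr, pos). The
min-P rule keeps the seed ("psig"); the max-CADD rule keeps the most
deleterious member ("map"), ties broken by smaller P then position, with a
logged min-P fallback when no member has a CADD score. Note the direction
of the sensitivity setting: recruiting at the *stringent* r² ≥ 0.1 absorbs
more partners per clump and therefore yields **fewer**, more independent
index SNPs, not more. Candidate pools are rsid-level unions across
phenotype GWAS (smallest-P occurrence kept, provenance retained);
cross-phenotype LD between pooled index SNPs is not re-clumped.

Gene mapping is positional only: a SNP inside a gene interval maps to it,
otherwise to the nearest gene on the chromosome within 250 kb (default),
equidistant genes all reported and flagged.

## Genetic scores

PRS = Σ β̂_j · dosage_ij over the candidate set, harmonized to the cohort's
effect alleles (swapped alleles contribute β(2−d)); variants absent from
the cohort are skipped and reported; missing dosages are mean-imputed at
twice the cohort effect-allele frequency (the standard PRS convention —
"2×MAF" read literally would corrupt scores for frequencies above 0.5).
Standardization is `(x − mean_ref)/sd_ref` against the European-labeled
reference subset, population (ddof = 0) SD.

APOE-ε4 counts derive only from rs429358 and rs7412 (ε4 = C/C across the
two sites per haplotype, ε3 = T/C, ε2 = T/T). Unphased genotypes determine
the diplotype except the double heterozygote, resolved as ε2/ε4 (count 1,
flagged ambiguous) since ε1 is vanishingly rare; combinations forcing an
ε1 haplotype are counted parsimoniously and flagged. Dosages more than 0.2
from an integer flag low confidence.

## Cohort phenotyping

Eligibility: complete demographics, ≥2 encounters strictly after the 55th
birthday, last encounter before age 90 (records are censored there).
Cases: ≥1 encounter with an ICD-10 code matching a dementia prefix
(default G30, F01–F03, G31), first such encounter strictly after 55 (that
age is the onset age). Controls: no exclusion-prefix code anywhere
(dementia prefixes plus F05/F06/R41 by default, fully configurable — the
published exclusion-phenotype list is an external input, not hard-coded),
last visit at ≥70, span ≥5 years, ≥1 encounter per span-year
(span-normalized, not calendar years). Ages are exact to the day with
365.25-day years; prefix matching means G30 covers G30.9.

## The synthetic data-generating process

* **Genotypes.** Per-variant ancestral frequencies ~ U(0.08, 0.92);
  population frequencies from a Balding–Nichols Beta draw with an
  F_ST-like divergence parameter per population (defaults 0.02/0.12/0.06
  for the EA/AA/HLA groups). Haplotypes are latent Gaussian AR(1)
  processes within fixed-length blocks (default 10 SNPs, latent
  correlation 0.7), thresholded at the frequency quantile; dosage = sum of
  two haplotypes. Adjacent-variant correlation decays with distance and is
  zero across blocks. Causal and rs429358 frequencies are clamped to
  [0.15, 0.85] in every population — GWAS risk loci are common variants by
  construction, and an unclamped draw can leave a planted locus nearly
  monomorphic in one group, silently changing the study design; rs7412
  keeps its natural low frequency so ε1-forcing genotype combinations stay
  rare.
* **GWAS summary statistics.** Marginal β_j = Σ_k ρ_jk β_k over planted
  causal effects, with ρ the *exact* dosage correlation of the generating
  process (a tetrachoric-style identity on the latent AR(1)), SE =
  1/√(2f(1−f)n), Gaussian estimation noise, Wald P-values. Using empirical
  panel LD instead injects √n_panel noise that large GWAS sample sizes
  amplify into spurious genome-wide hits. CADD scores are Gamma(2,3) with
  causal variants offset into the upper tail, so max-CADD selection is
  informative.
* **EHR.** Liability: logit(p) = intercept + 0.05·(age−mean) +
  0.2·(male−mean) + 0.3·PC1 + Σ β_j·(dosage−mean), with PC1 and each
  variant's contribution centered within its population (so frequency
  divergence does not shift group prevalence) and the intercept calibrated
  numerically to the target marginal prevalence (0.20 by default —
  matching the ~20% case fraction of eligible biobank group samples;
  Jensen's inequality shifts a plugged-in logit(0.2) upward otherwise).
  Encounters: Poisson(2/year) over a U(6, 14)-year span ending at a fixed
  index date, birth years 1934–1952 (ages ≈ 70–89), so the eligibility
  filters retain most patients. Cases receive G30 or F03 at a generated
  onset encounter strictly after 55; other encounters carry filler codes.
* **What it does not emulate:** realistic haplotype phasing or
  recombination maps, rare variants, imputation error, comorbidity code
  structure, missing-not-at-random EHR patterns, genotype–demographic
  confounding, or APOE haplotype structure beyond two loci. Passing tests
  establish internal correctness and qualitative behavior of the method,
  not expected performance on real biobanks.

### The ancestry-heterogeneity scenario

The scenario behind the central comparison encodes the portability
literature explicitly: the APOE effect (0.8 log-odds) is shared across
groups; the ten EA-discovered causal effects (0.2–0.6) are attenuated in
the AA group with *per-locus* multipliers 0.0–1.1 (mean ≈ 0.5; uniform
attenuation would be absorbed by the PRS's scalar refit and models no
tagging heterogeneity) and ×0.6 in HLA; and six AA-specific loci of 0.6
log-odds (the scale reported for African-ancestry AD loci such as ABCA7,
OR ≈ 1.8) are discoverable only by a second, AA-ancestry GWAS. Cohorts are
1200 per population (~250 eligible cases per group), a realistic biobank
slice giving the within-group refit adequate power at 1:3. Under these
conditions a fixed EA-weighted PRS is structurally miscalibrated in AA
while the Elastic Net, drawing on the multi-GWAS candidate pool, refits
each SNP within the group — the direction the pipeline is designed to
demonstrate.

### Null scenario

Intercept-only liability (genetic and demographic coefficients zero) with
the symmetric age covariate. This isolates the machinery: any residual
discrimination would be leakage. Observed medians sit within 0.45–0.55
AUROC for all four families.

## Problem sizes used

Test and acceptance analyses run at reduced scale as the package's own
choice of desk-scale conditions: 200 paired permutation iterations for the
heterogeneity comparison, 100 in the acceptance script, 25 for null
calibration, 20 seeds × n=2000 for recovery, 10 seeds × n=8000 for the
offset contract. The `run_permutation` default remains 1000 iterations.

## Known limitations

* Greedy clumping depends on the P-value ordering; it is the field's
  standard but not a globally optimal partition.
* Cross-phenotype candidate pools are deduplicated by rsid only; LD
  *between* phenotypes' index SNPs is not re-clumped.
* The FISTA solver is dense; pools beyond ~10⁴ features would want a
  coordinate or screening strategy.
* Permutation CIs condition on the fixed case set (see above); they
  understate total sampling variability for small case counts.
* Transfer between cohorts assumes rsid-level feature identity; missing
  model SNPs in a target cohort must be imputed or zero-filled upstream.
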