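"""Synthetic multi-ancestry genotype + GWAS + EHR study generator.

The generator produces everything the pipeline consumes, with known ground
truth:

* **Genotypes** — per-population allele frequencies drawn around a shared
  ancestral frequency with a Balding-Nichols-style divergence parameter
  (an F_ST-like quantity), and haplotypes generated from a latent Gaussian
  AR(1) process within fixed-length LD blocks, giving adjacent-variant
  correlation that decays with distance and vanishes across block
  boundaries.
* **GWAS summary statistics** — marginal effects induced analytically from
  the planted causal effects through the reference LD matrix
  (``beta_j = sum_k rho_jk * beta_k``) plus sampling noise at the stated
  GWAS sample size; P-values from the Wald statistic.  CADD scores are
  drawn positive, with causal variants placed in the upper tail so that
  max-CADD index selection is informative.
* **EHR records** — a logistic liability over age, sex, genotype PCs, and
  planted per-variant effects decides case status; cases receive a dementia
  ICD-10 code (G30 or F03) at a generated onset encounter after age 55.

Two designated variants carry the real APOE coordinates and rsIDs
(rs429358 chr19:44908684, rs7412 chr19:44912079) in their own terminal LD
block so APOE-e4 counting is exercised end to end.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logit as _logit

from .data_io import GenotypeDosageMatrix, GwasSummaryTable, PatientRecord

APOE_E4_RSID = "rs429358"   # effect allele C (e4-defining)
APOE_E2_RSID = "rs7412"     # effect allele T (e2-defining)
APOE_POSITIONS = {APOE_E4_RSID: 44908684, APOE_E2_RSID: 44912079}
DEMENTIA_ONSET_CODES = ("G30", "F03")
FILLER_CODES = ("Z00.0", "I10", "E11.9", "M54.5", "J06.9", "K21.9")
INDEX_DATE = _dt.date(2023, 1, 1)


class ConfigError(ValueError):
    """A simulation-configuration field is invalid; the message names it."""


@dataclass(frozen=True)
class PopulationSpec:
    """One source population: label, reference-panel and cohort sizes, and
    allele-frequency divergence from the shared ancestral frequency
    (0 = identical to ancestral; typical continental values 0.02-0.15)."""

    label: str
    n_reference: int
    n_cohort: int
    divergence: float

    def validate(self) -> None:
        if self.n_reference < 0 or self.n_cohort < 0:
            raise ConfigError(f"population {self.label}: negative sample size")
        if not 0.0 <= self.divergence < 1.0:
            raise ConfigError(
                f"population {self.label}: divergence must be in [0,1), "
                f"got {self.divergence}")


@dataclass(frozen=True)
class CausalEffect:
    """A planted causal variant: SNP index, phenotype it drives, log-odds
    effect per effect-allele copy, and optional population multipliers."""

    snp_index: int
    phenotype: str
    effect: float
    pop_multipliers: dict[str, float] = field(default_factory=dict)

    def effect_in(self, population: str) -> float:
        return self.effect * self.pop_multipliers.get(population, 1.0)


@dataclass(frozen=True)
class DemographicEffects:
    """Log-odds liability contributions per unit of each demographic."""

    age_per_year: float = 0.05
    sex_male: float = 0.2
    pc_unit: float = 0.3


@dataclass(frozen=True)
class EhrParams:
    """Encounter-history shape: mean encounters/year, record-span range in
    years, and cohort birth-year range (ages are taken at a fixed index
    date)."""

    encounter_rate: float = 2.0
    span_years: tuple[float, float] = (6.0, 14.0)
    birth_year_range: tuple[int, int] = (1934, 1952)

    def validate(self) -> None:
        if self.encounter_rate <= 0:
            raise ConfigError("ehr_params.encounter_rate must be positive")
        if not 0 < self.span_years[0] <= self.span_years[1]:
            raise ConfigError("ehr_params.span_years must be 0 < lo <= hi")
        if self.birth_year_range[0] > self.birth_year_range[1]:
            raise ConfigError("ehr_params.birth_year_range reversed")


@dataclass
class SimulationConfig:
    seed: int = 0
    populations: list[PopulationSpec] = field(default_factory=lambda: [
        PopulationSpec("EA", 250, 600, 0.02),
        PopulationSpec("AA", 250, 600, 0.12),
        PopulationSpec("HLA", 250, 600, 0.06),
    ])
    n_snps: int = 300
    ld_block_length: int = 10
    within_block_corr: float = 0.7
    causal_plan: list[CausalEffect] = field(default_factory=list)
    gwas_n: float = 5e4
    gwas_ancestry: dict[str, str] = field(default_factory=dict)
    demographic_effects: DemographicEffects = field(
        default_factory=DemographicEffects)
    baseline_prevalence: float = 0.20
    ehr_params: EhrParams = field(default_factory=EhrParams)
    missing_rate: float = 0.0
    apoe_e4_effect: float = 0.0  # log-odds per rs429358 C allele in liability
    # scales every genetic liability contribution (0 = phenotype independent
    # of genotype while the GWAS tables still nominate the planted SNPs)
    liability_effect_scale: float = 1.0

    def validate(self) -> None:
        if not self.populations:
            raise ConfigError("populations must be non-empty")
        for p in self.populations:
            p.validate()
        if self.n_snps < 4:
            raise ConfigError("n_snps must be >= 4 (two blocks incl. APOE)")
        if self.ld_block_length < 1:
            raise ConfigError("ld_block_length must be >= 1")
        if not 0.0 <= self.within_block_corr < 1.0:
            raise ConfigError("within_block_corr must be in [0, 1)")
        if self.gwas_n <= 0:
            raise ConfigError("gwas_n must be positive")
        if not 0.0 < self.baseline_prevalence < 1.0:
            raise ConfigError("baseline_prevalence must be in (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must be in [0, 1)")
        self.ehr_params.validate()
        labels = {p.label for p in self.populations}
        for pheno, anc in self.gwas_ancestry.items():
            if anc not in labels:
                raise ConfigError(
                    f"gwas_ancestry[{pheno!r}]={anc!r} not a population label")
        for c in self.causal_plan:
            if not 0 <= c.snp_index < self.n_snps:
                raise ConfigError(
                    f"causal_plan snp_index {c.snp_index} out of range")

    # APOE variants occupy the last two columns as their own chr19 block.
    @property
    def apoe_indices(self) -> tuple[int, int]:
        return self.n_snps - 2, self.n_snps - 1

    def blocks(self) -> list[np.ndarray]:
        """Column-index arrays of the LD blocks (final partial block kept;
        the two APOE columns always form their own terminal block)."""
        body = np.arange(self.n_snps - 2)
        out = [body[i:i + self.ld_block_length]
               for i in range(0, len(body), self.ld_block_length)]
        out.append(np.arange(self.n_snps - 2, self.n_snps))
        return out


@dataclass
class SimulatedStudy:
    """All generated inputs plus ground truth for one synthetic study."""

    config: SimulationConfig
    reference_panel: GenotypeDosageMatrix
    cohort_genotypes: GenotypeDosageMatrix
    gwas_tables: list[GwasSummaryTable]
    patient_records: list[PatientRecord]
    truth: dict


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _variant_table(config: SimulationConfig) -> pd.DataFrame:
    n = config.n_snps
    i4, i2 = config.apoe_indices
    chrom = np.full(n, "1", dtype=object)
    pos = 10_000 * (np.arange(n) + 1)
    rsid = np.array([f"rs{900000 + j}" for j in range(n)], dtype=object)
    eff = np.full(n, "", dtype=object)
    oth = np.full(n, "", dtype=object)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    pairs = [("A", "C"), ("A", "G"), ("C", "T"), ("G", "T")]
    choice = rng.integers(0, len(pairs), size=n)
    for j in range(n):
        eff[j], oth[j] = pairs[choice[j]]
    chrom[[i4, i2]] = "19"
    pos[i4] = APOE_POSITIONS[APOE_E4_RSID]
    pos[i2] = APOE_POSITIONS[APOE_E2_RSID]
    rsid[i4], rsid[i2] = APOE_E4_RSID, APOE_E2_RSID
    eff[i4], oth[i4] = "C", "T"
    eff[i2], oth[i2] = "T", "C"
    return pd.DataFrame({"chr": chrom, "pos": pos, "rsid": rsid,
                         "effect_allele": eff, "other_allele": oth})


def _population_freqs(config: SimulationConfig, rng: np.random.Generator,
                      ) -> dict[str, np.ndarray]:
    """Balding-Nichols frequencies: per-population Beta draws around a shared
    ancestral frequency, spread controlled by the divergence parameter."""
    n = config.n_snps
    ancestral = rng.uniform(0.08, 0.92, size=n)
    i4, i2 = config.apoe_indices
    ancestral[i4] = 0.15   # rs429358-C (e4) frequency
    ancestral[i2] = 0.08   # rs7412-T (e2) frequency
    freqs = {}
    for popspec in config.populations:
        F = popspec.divergence
        if F == 0.0:
            f = ancestral.copy()
        else:
            a = ancestral * (1 - F) / F
            b = (1 - ancestral) * (1 - F) / F
            f = rng.beta(a, b)
        freqs[popspec.label] = np.clip(f, 0.01, 0.99)
    return freqs


def _study_freqs(config: SimulationConfig,
                 rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Population frequencies with causal and APOE variants clamped to the
    common range [0.15, 0.85] in every population: GWAS risk loci are
    common variants by construction (rare ones would not reach discovery),
    and the e4 allele segregates at 0.1-0.2 across continental groups."""
    freqs = _population_freqs(config, rng)
    # rs7412 (e2-defining) stays at its low natural frequency; raising it
    # would manufacture impossible e1 haplotype combinations
    anchor = sorted({c.snp_index for c in config.causal_plan}
                    | {config.apoe_indices[0]} - {config.apoe_indices[1]})
    for f in freqs.values():
        f[anchor] = np.clip(f[anchor], 0.15, 0.85)
    return freqs


def _draw_dosages(freq: np.ndarray, n_ind: int, blocks: list[np.ndarray],
                  rho: float, rng: np.random.Generator) -> np.ndarray:
    """Two latent-Gaussian AR(1) haplotypes per individual, thresholded at
    the allele-frequency quantile."""
    n_snps = len(freq)
    thresh = stats.norm.ppf(freq)
    dos = np.zeros((n_ind, n_snps))
    for _hap in range(2):
        z = np.empty((n_ind, n_snps))
        for block in blocks:
            eps = rng.standard_normal((n_ind, len(block)))
            zb = np.empty_like(eps)
            zb[:, 0] = eps[:, 0]
            for t in range(1, len(block)):
                zb[:, t] = rho * zb[:, t - 1] + np.sqrt(1 - rho ** 2) * eps[:, t]
            z[:, block] = zb
        dos += (z < thresh[None, :])
    return dos


def simulate_genotypes(config: SimulationConfig,
                       ) -> tuple[GenotypeDosageMatrix, GenotypeDosageMatrix]:
    """Generate the labeled reference panel and the analysis cohort.

    Returns ``(reference_panel, cohort_genotypes)``.  Dosages are hard calls
    in {0,1,2}; optional missingness (``config.missing_rate``) is applied to
    the cohort only, uniformly at random.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    variants = _variant_table(config)
    freqs = _study_freqs(config, rng)
    blocks = config.blocks()
    rho = config.within_block_corr

    ref_parts, ref_pops, coh_parts, coh_pops = [], [], [], []
    for popspec in config.populations:
        f = freqs[popspec.label]
        ref_parts.append(_draw_dosages(f, popspec.n_reference, blocks, rho, rng))
        ref_pops += [popspec.label] * popspec.n_reference
        coh_parts.append(_draw_dosages(f, popspec.n_cohort, blocks, rho, rng))
        coh_pops += [popspec.label] * popspec.n_cohort

    ref_dos = np.vstack(ref_parts)
    coh_dos = np.vstack(coh_parts)
    if config.missing_rate > 0:
        mask = rng.random(coh_dos.shape) < config.missing_rate
        coh_dos = np.where(mask, np.nan, coh_dos)

    ref = GenotypeDosageMatrix(
        [f"ref{i:05d}" for i in range(len(ref_dos))], variants.copy(),
        ref_dos, populations=ref_pops)
    cohort = GenotypeDosageMatrix(
        [f"pt{i:05d}" for i in range(len(coh_dos))], variants.copy(), coh_dos)
    cohort._true_populations = coh_pops  # ground truth, not an API field
    return ref, cohort


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

def _dosage_corr(f1: float, f2: float, r_latent: float) -> float:
    """Exact dosage correlation between two variants generated by
    thresholding latent Gaussians with correlation ``r_latent`` at the
    allele-frequency quantiles (a tetrachoric-style identity)."""
    if r_latent == 0.0:
        return 0.0
    if r_latent == 1.0 and f1 == f2:
        return 1.0
    q1, q2 = stats.norm.ppf(f1), stats.norm.ppf(f2)
    p11 = stats.multivariate_normal(
        mean=[0.0, 0.0], cov=[[1.0, r_latent], [r_latent, 1.0]]).cdf([q1, q2])
    return float((p11 - f1 * f2)
                 / np.sqrt(f1 * (1 - f1) * f2 * (1 - f2)))


def simulate_gwas_summary(config: SimulationConfig,
                          reference_panel: GenotypeDosageMatrix,
                          ) -> list[GwasSummaryTable]:
    """Analytic marginal GWAS tables, one per phenotype in the causal plan.

    Marginal effect of variant j is ``sum_k rho_jk * beta_k`` over planted
    causal variants k, with rho the exact dosage correlation of the
    generating process in the GWAS ancestry (block-diagonal by
    construction).  The standard error scales as ``1/sqrt(2 f(1-f) n)``,
    the estimate adds Gaussian noise at that SE, and the P-value is the
    two-sided Wald test.
    """
    config.validate()
    if config.gwas_n <= 0:  # re-checked: callers may mutate post-validate
        raise ConfigError("gwas_n must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    phenos: dict[str, list[CausalEffect]] = {}
    for c in config.causal_plan:
        phenos.setdefault(c.phenotype, []).append(c)
    if not phenos:
        phenos = {"null": []}

    # population allele frequencies are the first draw on the genotype
    # stream, so they can be reproduced here deterministically
    freq_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    pop_freqs = _study_freqs(config, freq_rng)
    blocks = config.blocks()

    tables = []
    default_anc = config.populations[0].label
    for pheno, effects in sorted(phenos.items()):
        ancestry = config.gwas_ancestry.get(pheno, default_anc)
        f = np.clip(pop_freqs[ancestry], 1e-3, 1 - 1e-3)
        marginal = np.zeros(config.n_snps)
        for c in effects:
            k = c.snp_index
            block = next(b for b in blocks if k in b)
            for j in block:
                r_lat = config.within_block_corr ** abs(
                    int(np.flatnonzero(block == j)[0])
                    - int(np.flatnonzero(block == k)[0]))
                rho = _dosage_corr(f[j], f[k], r_lat)
                marginal[j] += rho * c.effect_in(ancestry)
        se = 1.0 / np.sqrt(2.0 * f * (1 - f) * config.gwas_n)
        beta_hat = marginal + rng.normal(0.0, se)
        z = beta_hat / se
        pval = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
        cadd = rng.gamma(2.0, 3.0, size=config.n_snps)
        for c in effects:
            cadd[c.snp_index] = 15.0 + rng.gamma(2.0, 3.0)
        t = reference_panel.variants.copy()
        t["beta"] = beta_hat
        t["se"] = se
        t["pvalue"] = pval
        t["cadd"] = cadd
        tables.append(GwasSummaryTable(pheno, ancestry, t))
    return tables


# ---------------------------------------------------------------------------
# EHR
# ---------------------------------------------------------------------------

def _cohort_pcs(dosages: np.ndarray, k: int = 2) -> np.ndarray:
    """Top-k unit-variance PC scores of the (mean-imputed) cohort matrix."""
    X = np.where(np.isnan(dosages),
                 np.nanmean(dosages, axis=0, keepdims=True), dosages)
    X = X - X.mean(axis=0)
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = u[:, :k] * s[:k]
    sd = scores.std(axis=0)
    sd[sd == 0] = 1.0
    return scores / sd


def simulate_ehr(config: SimulationConfig,
                 cohort_genotypes: GenotypeDosageMatrix,
                 ) -> tuple[list[PatientRecord], dict]:
    """Generate encounter histories; returns ``(records, truth)``.

    Liability: ``logit(p_i) = logit(prevalence) + beta_age*age_c +
    beta_sex*male_c + beta_pc*PC1_c + sum_j beta_j*dosage_c`` with all
    covariates mean-centered so the configured baseline prevalence is the
    approximate marginal case rate.  Cases get a dementia code at an onset
    encounter strictly after age 55.
    """
    config.validate()
    rsids = set(cohort_genotypes.variants["rsid"])
    for needed in (APOE_E4_RSID, APOE_E2_RSID):
        if needed not in rsids:
            raise ValueError(f"cohort genotypes missing APOE variant {needed}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    n = cohort_genotypes.n_samples
    de = config.demographic_effects
    ehr = config.ehr_params

    y0, y1 = ehr.birth_year_range
    birth_days = rng.integers(0, (y1 - y0 + 1) * 365, size=n)
    birth_dates = [_dt.date(y0, 1, 1) + _dt.timedelta(days=int(d))
                   for d in birth_days]
    ages = np.array([(INDEX_DATE - b).days / 365.25 for b in birth_dates])
    male = rng.random(n) < 0.5
    pcs = _cohort_pcs(cohort_genotypes.dosages)
    # the PC liability effect models population structure *within* each
    # ancestry group (as do the model covariates); centering PC1 within the
    # true populations keeps baseline prevalence comparable across groups
    pops_arr = np.asarray(getattr(cohort_genotypes, "_true_populations",
                                  ["_"] * n))
    pc1 = pcs[:, 0].copy()
    for lab in np.unique(pops_arr):
        idx = pops_arr == lab
        pc1[idx] -= pc1[idx].mean()

    dos = np.where(np.isnan(cohort_genotypes.dosages),
                   np.nanmean(cohort_genotypes.dosages, axis=0, keepdims=True),
                   cohort_genotypes.dosages)
    pops = getattr(cohort_genotypes, "_true_populations",
                   [config.populations[0].label] * n)
    genetic = np.zeros(n)
    plan = list(config.causal_plan)
    if config.apoe_e4_effect:
        i4 = int(np.flatnonzero(
            cohort_genotypes.variants["rsid"] == APOE_E4_RSID)[0])
        plan.append(CausalEffect(i4, "dementia", config.apoe_e4_effect))
    # center each variant's contribution within its population so that
    # allele-frequency divergence does not shift group-level prevalence
    for c in plan:
        col = dos[:, c.snp_index].copy()
        for lab in np.unique(pops_arr):
            idx = pops_arr == lab
            col[idx] -= col[idx].mean()
        eff = np.array([c.effect_in(p) for p in pops])
        genetic += eff * col
    genetic *= config.liability_effect_scale

    eta0 = (de.age_per_year * (ages - ages.mean())
            + de.sex_male * (male - male.mean())
            + de.pc_unit * pc1
            + genetic)
    # calibrate the intercept so the mean liability hits the target
    # prevalence exactly (Jensen's inequality shifts it otherwise)
    from scipy.optimize import brentq
    target = config.baseline_prevalence
    intercept = brentq(
        lambda c: np.mean(1.0 / (1.0 + np.exp(-(c + eta0)))) - target,
        _logit(target) - 10.0, _logit(target) + 10.0)
    prob = 1.0 / (1.0 + np.exp(-(intercept + eta0)))
    case = rng.random(n) < prob

    records, onset_ages = [], {}
    for i, sid in enumerate(cohort_genotypes.samples):
        span = min(rng.uniform(*ehr.span_years), ages[i] - 40.0)
        start_age = ages[i] - span
        n_enc = max(1, rng.poisson(ehr.encounter_rate * span))
        enc_ages = np.sort(rng.uniform(start_age, ages[i], size=n_enc))
        enc_codes = []
        for _a in enc_ages:
            k = rng.integers(0, 3)
            enc_codes.append(list(rng.choice(FILLER_CODES, size=k,
                                             replace=False)))
        if case[i]:
            onset_lo = max(55.0 + 1e-3, start_age)
            onset = rng.uniform(onset_lo, max(onset_lo + 1e-3, ages[i]))
            code = DEMENTIA_ONSET_CODES[rng.integers(0, 2)]
            later = np.flatnonzero(enc_ages >= onset)
            if len(later):
                enc_codes[later[0]].append(code)
            else:
                enc_ages = np.append(enc_ages, onset)
                enc_codes.append([code])
            onset_ages[sid] = float(max(onset, 55.0 + 1e-3))
        encounters = [
            (birth_dates[i] + _dt.timedelta(days=int(round(a * 365.25))),
             codes)
            for a, codes in zip(enc_ages, enc_codes)]
        records.append(PatientRecord(sid, birth_dates[i],
                                     "male" if male[i] else "female",
                                     encounters))

    truth = {
        "case_labels": {s: bool(c) for s, c in
                        zip(cohort_genotypes.samples, case)},
        "onset_ages": onset_ages,
        "liability_prob": {s: float(p) for s, p in
                           zip(cohort_genotypes.samples, prob)},
        "populations": {s: p for s, p in zip(cohort_genotypes.samples, pops)},
        "causal": [{"rsid": str(cohort_genotypes.variants["rsid"][c.snp_index]),
                    "phenotype": c.phenotype, "effect": c.effect,
                    "pop_multipliers": dict(c.pop_multipliers)}
                   for c in plan],
    }
    return records, truth


# ---------------------------------------------------------------------------
# gene annotation and gene sets
# ---------------------------------------------------------------------------

def synthetic_gene_annotation(config: SimulationConfig) -> pd.DataFrame:
    """One synthetic gene per LD block (1-based inclusive intervals) spanning
    that block's variants, plus the real APOE locus interval on chr19, so
    positional SNP-to-gene mapping has a well-defined truth."""
    rows = []
    for b, block in enumerate(config.blocks()[:-1]):
        lo = 10_000 * (int(block[0]) + 1) - 2_000
        hi = 10_000 * (int(block[-1]) + 1) + 2_000
        rows.append((f"GENE{b + 1:03d}", "1", lo, hi))
    rows.append(("APOE", "19", 44905791, 44909393))
    rows.append(("APOC1", "19", 44914325, 44919349))
    return pd.DataFrame(rows, columns=["gene", "chr", "start", "end"])


def causal_block_genes(config: SimulationConfig) -> set[str]:
    """Names of the synthetic genes whose blocks host planted causal SNPs."""
    genes = set()
    for c in config.causal_plan:
        genes.add(f"GENE{c.snp_index // config.ld_block_length + 1:03d}")
    return genes


def synthetic_gene_sets(config: SimulationConfig,
                        rng: np.random.Generator | None = None,
                        ) -> dict[str, list[str]]:
    """Gene-set collections over the synthetic annotation: one set enriched
    in causal-block genes, plus random sets of matched sizes."""
    rng = rng or np.random.default_rng(np.random.SeedSequence(
        [config.seed, 11]))
    ann = synthetic_gene_annotation(config)
    universe = ann["gene"].tolist()
    causal = sorted(causal_block_genes(config) | {"APOE"})
    extra = [g for g in universe if g not in causal]
    sets = {"CAUSAL_PATHWAY": causal
            + list(rng.choice(extra, size=min(3, len(extra)), replace=False))}
    for s in range(4):
        size = int(rng.integers(5, 12))
        sets[f"RANDOM_SET_{s + 1}"] = list(
            rng.choice(universe, size=size, replace=False))
    return sets


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

def default_causal_plan(config_n_snps: int = 300) -> list[CausalEffect]:
    """The default planted architecture: ten causal SNPs for two phenotypes
    with log-odds effects 0.2-0.6, spread over distinct LD blocks."""
    idx = [5, 35, 65, 95, 125, 155, 185, 215, 245, 275]
    effects = [0.2, 0.25, 0.3, 0.35, 0.4, 0.45, 0.5, 0.55, 0.6, 0.4]
    plan = []
    for i, (j, e) in enumerate(zip(idx, effects)):
        pheno = "AD" if i < 6 else "LBD"
        plan.append(CausalEffect(j, pheno, e))
    return plan


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The standard synthetic study: three ancestry groups, 300 SNPs in
    10-SNP LD blocks, ten planted causal SNPs plus an APOE (rs429358)
    effect of 0.8 log-odds carried by the AD GWAS — the APOE locus is the
    strongest AD association, so it belongs in the summary statistics and
    hence in every candidate pool — at baseline prevalence 0.20."""
    cfg = SimulationConfig(seed=seed, **overrides)
    if not cfg.causal_plan:
        cfg.causal_plan = default_causal_plan(cfg.n_snps)
        cfg.causal_plan.append(
            CausalEffect(cfg.apoe_indices[0], "AD", 0.8))
    return cfg


def heterogeneous_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The ancestry-heterogeneous scenario behind the central claim.

    The EA-referenced AD GWAS effects are attenuated in the AA and HLA
    groups (alternating multipliers), and a second AD GWAS conducted in AA
    ancestry carries four AA-specific risk loci that the EA GWAS cannot
    see.  A single fixed-weight EA PRS is therefore miscalibrated in AA —
    it overweights attenuated loci and misses the AA-specific ones — while
    APOE (rs429358, shared across groups) and per-SNP refitting within the
    group can exploit the full multi-GWAS candidate pool.

    Cohorts are sized at 1200 per population (a realistic biobank slice;
    ~250 eligible cases per group) so the within-group refit has adequate
    power at the 1:3 resampling ratio."""
    cfg = default_config(seed=seed, **overrides)
    if "populations" not in overrides:
        cfg.populations = [
            PopulationSpec(p.label, p.n_reference, 1200, p.divergence)
            for p in cfg.populations]
    # Per-locus attenuation of EA-discovered effects in the AA group:
    # tagging and effect-size differences vary locus by locus, so a fixed
    # EA-weighted score cannot be rescued by rescaling — the mechanism
    # behind the poor cross-ancestry portability of European-trained PRSs.
    aa_mults = (0.0, 0.9, 0.1, 0.7, 0.2, 1.1, 0.0, 0.8, 0.3, 1.0)
    plan = []
    k = 0
    for c in cfg.causal_plan:
        if c.snp_index == cfg.apoe_indices[0]:
            plan.append(c)  # APOE effect shared across ancestries
            continue
        plan.append(CausalEffect(
            c.snp_index, c.phenotype, c.effect,
            {"AA": aa_mults[k % len(aa_mults)], "HLA": 0.6}))
        k += 1
    # AA-specific risk loci, discoverable only by the AA-ancestry GWAS;
    # effect size on the scale reported for African-ancestry AD loci such
    # as ABCA7 (odds ratio ~1.8)
    for j in (12, 42, 72, 102, 132, 162):
        if j < cfg.n_snps - 2:
            plan.append(CausalEffect(
                j, "AD_AFR", 0.6, {"EA": 0.1, "HLA": 0.3}))
    cfg.causal_plan = plan
    cfg.gwas_ancestry = dict(cfg.gwas_ancestry, AD_AFR="AA")
    return cfg


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Run the full generator: genotypes, GWAS tables, EHR, truth."""
    ref, cohort = simulate_genotypes(config)
    gwas = simulate_gwas_summary(config, ref)
    records, truth = simulate_ehr(config, cohort)
    return SimulatedStudy(config, ref, cohort, gwas, records, truth)
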