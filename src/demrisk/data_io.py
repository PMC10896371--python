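"""Core data containers and I/O: GWAS summary tables, genotype dosage matrices,
patient encounter records, genotype QC, and cross-cohort variant intersection.

Conventions
-----------
* Coordinates are 1-based (VCF convention).  rsID is the primary join key
  across cohorts; positions are carried for reporting only.
* Dosages count copies of the *effect allele* and live in [0, 2]; missing
  dosages are NaN.  For VCF input the effect allele is the ALT allele.
* MAF is computed from non-missing dosages as ``min(f, 1-f)`` with
  ``f = mean(dosage) / 2``.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GWAS_COLUMNS = [
    "chr", "pos", "rsid", "effect_allele", "other_allele",
    "beta", "se", "pvalue",
]
_VALID_ALLELES = {"A", "C", "G", "T"}
_AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}
_ICD10_RE = re.compile(r"^[A-Z]\d{2}(\.\d{1,4})?$")


class SchemaError(ValueError):
    """A file or table does not match its required schema."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GwasSummaryTable:
    """Per-variant association statistics for one phenotype/ancestry GWAS.

    ``table`` columns: chr (str), pos (int, 1-based), rsid, effect_allele,
    other_allele, beta (per-effect-allele log-odds), se (>0), pvalue in (0,1],
    and optionally cadd (non-negative deleteriousness score, NaN if absent).
    """

    phenotype: str
    ancestry: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in GWAS_COLUMNS if c not in t.columns]
        if missing:
            raise SchemaError(f"GWAS table missing column(s): {missing}")
        if "cadd" not in t.columns:
            t = t.copy()
            t["cadd"] = np.nan
        t = t.astype({"chr": str, "pos": np.int64, "rsid": str,
                      "effect_allele": str, "other_allele": str,
                      "beta": float, "se": float, "pvalue": float,
                      "cadd": float})
        dup = t["rsid"][t["rsid"].duplicated()].unique()
        if len(dup):
            raise SchemaError(f"duplicate rsid(s) in GWAS table: {sorted(dup)[:10]}")
        bad = t[~t["effect_allele"].isin(_VALID_ALLELES)
                | ~t["other_allele"].isin(_VALID_ALLELES)
                | (t["effect_allele"] == t["other_allele"])]
        if len(bad):
            raise SchemaError(
                f"invalid allele pair(s) for rsid(s): {bad['rsid'].tolist()[:10]}")
        if ((t["pvalue"] <= 0) | (t["pvalue"] > 1)).any():
            raise SchemaError("pvalue outside (0, 1]")
        if (t["se"] <= 0).any():
            raise SchemaError("non-positive standard error")
        object.__setattr__(self, "table", t.reset_index(drop=True))

    @property
    def n_variants(self) -> int:
        return len(self.table)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GwasSummaryTable):
            return NotImplemented
        return (self.phenotype == other.phenotype
                and self.ancestry == other.ancestry
                and self.table.shape == other.table.shape
                and all(
                    np.allclose(self.table[c], other.table[c], equal_nan=True)
                    if self.table[c].dtype.kind == "f"
                    else (self.table[c] == other.table[c]).all()
                    for c in self.table.columns))


@dataclass
class GenotypeDosageMatrix:
    """Individuals x variants effect-allele dosage matrix with metadata.

    ``variants`` columns: chr, pos, rsid, effect_allele, other_allele, and
    optionally imputation_r2.  ``dosages`` has shape
    ``(n_samples, n_variants)`` with values in [0, 2] or NaN.
    ``populations`` optionally labels each sample (reference panels).
    """

    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray
    populations: list[str] | None = None

    def __post_init__(self) -> None:
        self.samples = list(map(str, self.samples))
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample ids are not unique")
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} != "
                f"({len(self.samples)}, {len(self.variants)})")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0) < -1e-9 or \
               np.nanmax(self.dosages, initial=0) > 2 + 1e-9:
                raise ValueError("dosages outside [0, 2]")
        self.variants = self.variants.reset_index(drop=True)
        if self.populations is not None:
            self.populations = list(map(str, self.populations))
            if len(self.populations) != len(self.samples):
                raise ValueError("populations length != samples length")

    # -- derived per-variant statistics ------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def allele_freq(self) -> np.ndarray:
        """Effect-allele frequency per variant from non-missing dosages."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.allele_freq()
        return np.minimum(f, 1.0 - f)

    def variant_missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def sample_missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=1)

    # -- subsetting --------------------------------------------------------
    def take_variants(self, idx: np.ndarray) -> "GenotypeDosageMatrix":
        idx = np.asarray(idx)
        return GenotypeDosageMatrix(
            self.samples, self.variants.iloc[idx].reset_index(drop=True),
            self.dosages[:, idx], self.populations)

    def take_samples(self, idx: np.ndarray) -> "GenotypeDosageMatrix":
        idx = np.asarray(idx)
        pops = [self.populations[i] for i in idx] if self.populations else None
        return GenotypeDosageMatrix(
            [self.samples[i] for i in idx],
            self.variants.copy(), self.dosages[idx, :], pops)

    def variant_index(self, rsids) -> np.ndarray:
        """Column indices of ``rsids``; KeyError on any absentee."""
        lookup = {r: i for i, r in enumerate(self.variants["rsid"])}
        missing = [r for r in rsids if r not in lookup]
        if missing:
            raise KeyError(f"variant(s) not in matrix: {missing[:10]}")
        return np.array([lookup[r] for r in rsids], dtype=int)


@dataclass
class PatientRecord:
    """One patient's demographics plus dated ICD-10-coded encounters."""

    patient_id: str
    birth_date: _dt.date
    sex: str  # "female" | "male"
    encounters: list[tuple[_dt.date, list[str]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be female/male, got {self.sex!r}")
        self.encounters = sorted(self.encounters, key=lambda e: e[0])
        for date, codes in self.encounters:
            if date < self.birth_date:
                raise ValueError(
                    f"{self.patient_id}: encounter {date} precedes birth")
            for code in codes:
                if not _ICD10_RE.match(code):
                    raise ValueError(f"invalid ICD-10 code {code!r}")

    def age_at(self, date: _dt.date) -> float:
        """Fractional age in years, exact to the day (365.25-day years)."""
        return (date - self.birth_date).days / 365.25


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_gwas_summary(path, phenotype: str, ancestry: str) -> GwasSummaryTable:
    """Read a GWAS summary-statistics TSV into a validated table.

    Required columns: chr, pos, rsid, effect_allele, other_allele, beta, se,
    pvalue; optional cadd.  Rows with unparseable numerics raise with the
    offending row number.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in GWAS_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    num_cols = ["pos", "beta", "se", "pvalue"] + (
        ["cadd"] if "cadd" in raw.columns else [])
    out = raw.copy()
    for col in num_cols:
        parsed = pd.to_numeric(raw[col], errors="coerce")
        bad = parsed.isna() & raw[col].notna()
        if col == "cadd":
            bad &= raw[col].str.strip().ne("")
        if bad.any():
            rows = (np.flatnonzero(bad) + 2).tolist()  # 1-based + header
            raise SchemaError(
                f"{path}: unparseable {col!r} at file row(s) {rows[:10]}")
        out[col] = parsed
    keep = GWAS_COLUMNS + (["cadd"] if "cadd" in out.columns else [])
    return GwasSummaryTable(phenotype, ancestry, out[keep])


def write_gwas_summary(gwas: GwasSummaryTable, path) -> None:
    t = gwas.table.copy()
    t["phenotype"] = gwas.phenotype
    t["ancestry"] = gwas.ancestry
    t.to_csv(path, sep="\t", index=False, na_rep="")


def read_genotypes(path, format: str = "dosage_tsv") -> GenotypeDosageMatrix:
    """Read genotypes from a dosage TSV or a VCF (DS field, or hard GT).

    VCF records must be bi-allelic; multi-allelic ALT raises instructing the
    caller to split the record first.
    """
    if format == "dosage_tsv":
        return _read_dosage_tsv(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


_META_COLS = ["chr", "pos", "rsid", "effect_allele", "other_allele"]


def _read_dosage_tsv(path) -> GenotypeDosageMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chr": str})
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    meta_cols = list(_META_COLS)
    if "imputation_r2" in df.columns:
        meta_cols.append("imputation_r2")
    sample_cols = [c for c in df.columns if c not in meta_cols]
    dosages = df[sample_cols].to_numpy(dtype=float).T  # samples x variants
    return GenotypeDosageMatrix(sample_cols, df[meta_cols], dosages)


def write_dosage_tsv(geno: GenotypeDosageMatrix, path) -> None:
    body = pd.DataFrame(geno.dosages.T, columns=geno.samples)
    pd.concat([geno.variants.reset_index(drop=True), body], axis=1) \
        .to_csv(path, sep="\t", index=False)


def _read_vcf(path) -> GenotypeDosageMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    meta, cols = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {var.CHROM}:{var.POS} "
                f"(ALT={','.join(var.ALT)}): split multi-allelic sites first")
        try:
            ds = var.format("DS")
        except KeyError:  # DS absent from the header entirely
            ds = None
        if ds is not None:
            col = ds[:, 0].astype(float)
        else:
            gt = var.genotype.array()[:, :2]
            col = np.where((gt < 0).any(axis=1), np.nan,
                           (gt > 0).sum(axis=1)).astype(float)
        rsid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        meta.append((str(var.CHROM), int(var.POS), rsid, var.ALT[0], var.REF))
        cols.append(col)
    variants = pd.DataFrame(meta, columns=_META_COLS)
    dosages = (np.stack(cols, axis=1) if cols
               else np.empty((len(samples), 0)))
    return GenotypeDosageMatrix(samples, variants, dosages)


def write_vcf(geno: GenotypeDosageMatrix, path) -> None:
    """Write a minimal uncompressed VCF with GT (rounded) + DS (exact) fields.

    The effect allele is written as ALT, the other allele as REF, matching the
    read-side convention.
    """
    order = np.lexsort((geno.variants["pos"].to_numpy(),
                        geno.variants["chr"].to_numpy()))
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                 'Description="Effect (ALT) allele dosage">\n')
        for c in pd.unique(geno.variants["chr"].to_numpy()[order]):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.samples) + "\n")
        for j in order:
            v = geno.variants.iloc[j]
            fields = []
            for d in geno.dosages[:, j]:
                if np.isnan(d):
                    fields.append("./.:.")
                else:
                    fields.append(f"{gt_codes[int(round(d))]}:{d:g}")
            fh.write(f"{v['chr']}\t{v['pos']}\t{v['rsid']}\t"
                     f"{v['other_allele']}\t{v['effect_allele']}\t.\t.\t.\t"
                     "GT:DS\t" + "\t".join(fields) + "\n")


def read_patient_records(path) -> list[PatientRecord]:
    """Read encounters TSV: patient_id, birth_date, sex, encounter_date,
    icd10_codes (semicolon-separated; empty allowed)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    need = ["patient_id", "birth_date", "sex", "encounter_date", "icd10_codes"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    records = []
    for pid, grp in df.groupby("patient_id", sort=False):
        birth = _dt.date.fromisoformat(grp["birth_date"].iloc[0])
        sex = grp["sex"].iloc[0]
        encounters = [
            (_dt.date.fromisoformat(r.encounter_date),
             [c for c in r.icd10_codes.split(";") if c])
            for r in grp.itertuples()]
        records.append(PatientRecord(str(pid), birth, sex, encounters))
    return records


def write_patient_records(records: list[PatientRecord], path) -> None:
    rows = []
    for rec in records:
        for date, codes in rec.encounters:
            rows.append((rec.patient_id, rec.birth_date.isoformat(), rec.sex,
                         date.isoformat(), ";".join(codes)))
    pd.DataFrame(rows, columns=["patient_id", "birth_date", "sex",
                                "encounter_date", "icd10_codes"]) \
        .to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Removal counts and ids per QC rule, in application order."""

    removed: dict[str, list[str]]  # rule -> removed sample/variant ids
    kept_samples: int = 0
    kept_variants: int = 0

    RULES = ("sample_missingness", "variant_missingness", "monomorphic",
             "strand_ambiguous", "imputation_r2", "maf")

    def counts(self) -> dict[str, int]:
        return {rule: len(self.removed.get(rule, [])) for rule in self.RULES}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(rule, len(ids), ";".join(ids))
             for rule, ids in ((r, self.removed.get(r, [])) for r in self.RULES)],
            columns=["rule", "count", "ids"])


def qc_filter(geno: GenotypeDosageMatrix,
              max_variant_missing: float = 0.05,
              max_sample_missing: float = 0.05,
              min_maf: float = 0.01,
              min_imputation_r2: float = 0.90,
              drop_strand_ambiguous: bool = True,
              drop_monomorphic: bool = True,
              ) -> tuple[GenotypeDosageMatrix, QCReport]:
    """Apply standard genotype QC in a fixed rule order.

    Order: sample missingness -> variant missingness -> monomorphic ->
    strand-ambiguous -> imputation r^2 -> MAF.  The imputation-r^2 rule is
    skipped with a logged notice when the matrix carries no ``imputation_r2``
    column (hard-called genotypes).  Removing every variant is reported, not
    raised.
    """
    for name, thr in [("max_variant_missing", max_variant_missing),
                      ("max_sample_missing", max_sample_missing),
                      ("min_maf", min_maf),
                      ("min_imputation_r2", min_imputation_r2)]:
        if not 0.0 <= thr <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {thr}")

    removed: dict[str, list[str]] = {}
    g = geno

    bad = g.sample_missing_rate() > max_sample_missing
    removed["sample_missingness"] = [g.samples[i] for i in np.flatnonzero(bad)]
    if bad.any():
        g = g.take_samples(np.flatnonzero(~bad))

    def _drop_variants(rule: str, bad: np.ndarray) -> None:
        nonlocal g
        removed[rule] = g.variants["rsid"].to_numpy()[bad].tolist()
        if bad.any():
            g = g.take_variants(np.flatnonzero(~bad))

    _drop_variants("variant_missingness",
                   g.variant_missing_rate() > max_variant_missing)
    if drop_monomorphic:
        _drop_variants("monomorphic", np.round(g.maf(), 9) == 0.0)
    if drop_strand_ambiguous:
        pairs = [frozenset((e, o)) for e, o in
                 zip(g.variants["effect_allele"], g.variants["other_allele"])]
        _drop_variants("strand_ambiguous",
                       np.array([p in _AMBIGUOUS_PAIRS for p in pairs]))
    if "imputation_r2" in g.variants.columns:
        r2 = g.variants["imputation_r2"].to_numpy(dtype=float)
        _drop_variants("imputation_r2",
                       ~np.isnan(r2) & (r2 < min_imputation_r2))
    else:
        logger.info("no imputation_r2 column: imputation-quality filter skipped")
    _drop_variants("maf", g.maf() < min_maf)

    if g.n_variants == 0:
        logger.warning("QC removed every variant")
    report = QCReport(removed, kept_samples=g.n_samples,
                      kept_variants=g.n_variants)
    return g, report


# ---------------------------------------------------------------------------
# variant intersection / harmonization
# ---------------------------------------------------------------------------

def intersect_variants(a: GenotypeDosageMatrix, b: GenotypeDosageMatrix,
                       ) -> tuple[GenotypeDosageMatrix, GenotypeDosageMatrix,
                                  list[str]]:
    """Restrict two cohorts to shared rsIDs with reconcilable alleles.

    Variants whose effect/other alleles are swapped between the cohorts have
    ``b``'s dosages flipped to ``2 - dosage`` and alleles harmonized to
    ``a``'s.  rsIDs whose alleles neither match nor swap are dropped and
    returned in the third element.
    """
    a_meta = a.variants.set_index("rsid")
    b_meta = b.variants.set_index("rsid")
    shared = [r for r in a_meta.index if r in set(b_meta.index)]
    keep_a, keep_b, flip, dropped = [], [], [], []
    for rsid in shared:
        ea, oa = a_meta.loc[rsid, ["effect_allele", "other_allele"]]
        eb, ob = b_meta.loc[rsid, ["effect_allele", "other_allele"]]
        if (ea, oa) == (eb, ob):
            keep_a.append(rsid); keep_b.append(rsid); flip.append(False)
        elif (ea, oa) == (ob, eb):
            keep_a.append(rsid); keep_b.append(rsid); flip.append(True)
        else:
            dropped.append(rsid)
    if dropped:
        logger.warning("intersect_variants: %d rsid(s) with irreconcilable "
                       "alleles dropped: %s", len(dropped), dropped[:10])
    if not keep_a:
        logger.warning("intersect_variants: empty intersection")
        empty_a = a.take_variants(np.array([], dtype=int))
        empty_b = b.take_variants(np.array([], dtype=int))
        return empty_a, empty_b, dropped

    ia = a.variant_index(keep_a)
    ib = b.variant_index(keep_b)
    a_out = a.take_variants(ia)
    b_out = b.take_variants(ib)
    flip = np.asarray(flip)
    if flip.any():
        b_out.dosages[:, flip] = 2.0 - b_out.dosages[:, flip]
        b_out.variants.loc[flip, ["effect_allele", "other_allele"]] = \
            a_out.variants.loc[flip, ["effect_allele", "other_allele"]].to_numpy()
    return a_out, b_out, dropped


def write_qc_report(report: QCReport, path) -> None:
    report.to_frame().to_csv(path, sep="\t", index=False)


def write_truth_json(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, default=str)
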