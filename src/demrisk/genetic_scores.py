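"""Polygenic risk scores and the APOE-e4 allele count.

The PRS for individual i is ``sum_j beta_j * dosage_ij`` over a candidate SNP
set, with weights harmonized to the cohort's effect alleles (swapped-allele
variants contribute ``beta * (2 - dosage)``).  Scores are standardized
against a reference population (typically the European-labeled reference
subset) so that the reference has mean 0 and SD 1.

The APOE-e4 count is derived solely from rs429358 and rs7412, the two
variants defining the e2/e3/e4 isoforms: an e4 haplotype carries C at
rs429358 together with C at rs7412; e2 carries T at both; e3 carries
rs429358-T with rs7412-C.  Unphased genotypes determine the diplotype except
for the double heterozygote (e2/e4 vs the vanishingly rare e1/e3), which is
resolved as e2/e4 (count 1) and flagged ambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_io import GenotypeDosageMatrix
from .snp_prioritization import SnpSet
from .synthetic_data import APOE_E2_RSID, APOE_E4_RSID

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# PRS
# ---------------------------------------------------------------------------

def compute_prs(geno: GenotypeDosageMatrix, snp_set: SnpSet,
                ) -> tuple[np.ndarray, list[str]]:
    """Raw PRS per sample; returns ``(scores, skipped_rsids)``.

    Variants absent from the cohort are skipped and reported.  Missing
    dosages are mean-imputed at twice the cohort effect-allele frequency.
    Raises when no variant is scorable.
    """
    geno_meta = geno.variants.set_index("rsid")
    scores = np.zeros(geno.n_samples)
    skipped: list[str] = []
    n_used = 0
    for _, snp in snp_set.table.iterrows():
        rsid = snp["rsid"]
        if rsid not in geno_meta.index:
            skipped.append(rsid)
            continue
        ea, oa = geno_meta.loc[rsid, ["effect_allele", "other_allele"]]
        j = int(geno.variant_index([rsid])[0])
        d = geno.dosages[:, j]
        d = np.where(np.isnan(d), np.nanmean(d), d)
        if (snp["effect_allele"], snp["other_allele"]) == (ea, oa):
            scores += snp["beta"] * d
        elif (snp["effect_allele"], snp["other_allele"]) == (oa, ea):
            scores += snp["beta"] * (2.0 - d)
        else:
            skipped.append(rsid)
            logger.warning("compute_prs: %s alleles irreconcilable; skipped",
                           rsid)
            continue
        n_used += 1
    if skipped:
        logger.info("compute_prs: %d variant(s) skipped: %s",
                    len(skipped), skipped[:10])
    if n_used == 0:
        raise ValueError("no scorable variants: every SNP in the set is "
                         "absent from or irreconcilable with the cohort")
    return scores, skipped


def standardize_scores(raw: np.ndarray, reference_raw: np.ndarray,
                       ) -> np.ndarray:
    """``(x - mean_ref) / sd_ref`` with population (ddof=0) reference SD."""
    mu = float(np.mean(reference_raw))
    sd = float(np.std(reference_raw))
    if sd == 0.0:
        raise ValueError("reference scores are constant; cannot standardize")
    return (np.asarray(raw, dtype=float) - mu) / sd


# ---------------------------------------------------------------------------
# APOE
# ---------------------------------------------------------------------------

@dataclass
class ApoeCount:
    """Per-sample e4 allele count in {0,1,2} with audit flags.

    ``ambiguous`` marks the rs429358 C/T + rs7412 C/T double heterozygote
    (resolved as e2/e4).  ``low_confidence`` marks dosages more than 0.2
    from an integer genotype.  ``rare_haplotype`` marks combinations that
    force an e1 haplotype (e.g. rs429358 C/C with rs7412 T/T), counted
    under the most parsimonious haplotype pair.
    """

    counts: np.ndarray
    ambiguous: np.ndarray
    low_confidence: np.ndarray
    rare_haplotype: np.ndarray


# (rs429358 C-count, rs7412 T-count) -> (e4 count, ambiguous, rare-e1)
_E4_TABLE: dict[tuple[int, int], tuple[int, bool, bool]] = {
    (0, 0): (0, False, False),   # e3/e3
    (0, 1): (0, False, False),   # e2/e3
    (0, 2): (0, False, False),   # e2/e2
    (1, 0): (1, False, False),   # e3/e4
    (1, 1): (1, True, False),    # e2/e4 (or rare e1/e3)
    (1, 2): (0, False, True),    # e1/e2
    (2, 0): (2, False, False),   # e4/e4
    (2, 1): (1, False, True),    # e1/e4
    (2, 2): (0, False, True),    # e1/e1
}


def apoe_e4_count(geno: GenotypeDosageMatrix) -> ApoeCount:
    """e4 allele counts from rs429358 and rs7412 dosages.

    Dosages are rounded half-away-from-zero to hard genotypes; a rounding
    distance above 0.2 sets the low-confidence flag.  Missing dosages raise.
    """
    rsids = set(geno.variants["rsid"])
    for needed in (APOE_E4_RSID, APOE_E2_RSID):
        if needed not in rsids:
            raise ValueError(f"APOE variant {needed} absent from genotypes")

    def _allele_counts(rsid: str, allele: str) -> tuple[np.ndarray, np.ndarray]:
        j = int(geno.variant_index([rsid])[0])
        ea = geno.variants["effect_allele"].iloc[j]
        oa = geno.variants["other_allele"].iloc[j]
        d = geno.dosages[:, j]
        if np.isnan(d).any():
            raise ValueError(f"missing dosages at {rsid}")
        if ea == allele:
            pass
        elif oa == allele:
            d = 2.0 - d
        else:
            raise ValueError(f"{rsid}: neither allele is {allele}")
        hard = np.floor(d + 0.5)  # half-away-from-zero for d >= 0
        return hard.astype(int), np.abs(d - hard)

    c429, dist1 = _allele_counts(APOE_E4_RSID, "C")
    t7412, dist2 = _allele_counts(APOE_E2_RSID, "T")
    low_conf = (dist1 > 0.2) | (dist2 > 0.2)

    counts = np.empty(geno.n_samples, dtype=int)
    ambiguous = np.zeros(geno.n_samples, dtype=bool)
    rare = np.zeros(geno.n_samples, dtype=bool)
    for i, key in enumerate(zip(c429, t7412)):
        counts[i], ambiguous[i], rare[i] = _E4_TABLE[key]
    if rare.any():
        logger.warning("apoe_e4_count: %d sample(s) with genotype "
                       "combinations requiring a rare e1 haplotype",
                       int(rare.sum()))
    return ApoeCount(counts, ambiguous, low_conf, rare)
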