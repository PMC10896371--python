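"""Risk-locus definition by P-value + LD clumping, index-SNP selection
(min-P "psig" and max-CADD "map" rules), cross-phenotype candidate pools,
and positional SNP-to-gene mapping.

Clumping follows the classic greedy scheme: among unassigned genome-wide
significant variants, seed a locus at the smallest P-value and recruit every
unassigned significant variant with r^2 >= threshold to the seed; repeat
until all significant variants belong to a locus.  r^2 is the squared
Pearson correlation of dosages in the ancestry-matched LD reference panel;
variants on different chromosomes have r^2 = 0 by definition, so loci never
span chromosomes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import GenotypeDosageMatrix, GwasSummaryTable

logger = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8
DEFAULT_R2 = 0.2
DEFAULT_MAX_GENE_DISTANCE = 250_000


@dataclass
class RiskLocus:
    locus_id: str
    phenotype: str
    members: list[str]          # rsids, seed first
    index_rsid: str             # min-P member (the seed)
    min_p: float
    chrom: str


@dataclass
class SnpSet:
    """A named candidate SNP set ("psig" = min-P indexes, "map" = max-CADD
    indexes), one variant per (locus, phenotype), with provenance."""

    kind: str
    table: pd.DataFrame  # rsid, chr, pos, alleles, beta, se, pvalue, cadd,
                         # phenotypes (';'-joined), locus_id

    @property
    def rsids(self) -> list[str]:
        return self.table["rsid"].tolist()

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

def ancestry_matched_panel(ld_panel: GenotypeDosageMatrix,
                           ancestry: str,
                           default_label: str | None = None,
                           ) -> GenotypeDosageMatrix:
    """The reference subset whose population label matches the GWAS
    ancestry; falls back to ``default_label`` then to the whole panel."""
    if ld_panel.populations is None:
        return ld_panel
    pops = np.asarray(ld_panel.populations)
    for lab in (ancestry, default_label):
        if lab is not None and (pops == lab).any():
            if lab != ancestry:
                logger.info("LD ancestry %r absent; using %r subset",
                            ancestry, lab)
            return ld_panel.take_samples(np.flatnonzero(pops == lab))
    logger.info("LD ancestry %r absent from panel; using all samples",
                ancestry)
    return ld_panel


def pairwise_r2(panel: GenotypeDosageMatrix, rsids: list[str]) -> np.ndarray:
    """Squared Pearson dosage correlation among ``rsids`` in the panel;
    cross-chromosome entries are 0 and constant variants correlate with
    nothing."""
    idx = panel.variant_index(rsids)
    X = panel.dosages[:, idx]
    X = np.where(np.isnan(X), np.nanmean(X, axis=0, keepdims=True), X)
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    denom = np.outer(sd, sd)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ Xc) / len(X) / denom
    r2 = np.nan_to_num(r ** 2, nan=0.0)
    chroms = panel.variants["chr"].to_numpy()[idx]
    same_chr = chroms[:, None] == chroms[None, :]
    r2 = np.where(same_chr, r2, 0.0)
    np.fill_diagonal(r2, 1.0)
    return r2


# ---------------------------------------------------------------------------
# clumping
# ---------------------------------------------------------------------------

def define_risk_loci(gwas: GwasSummaryTable,
                     ld_panel: GenotypeDosageMatrix,
                     p_thresh: float = GENOME_WIDE_P,
                     r2_thresh: float = DEFAULT_R2,
                     default_ld_label: str | None = None,
                     ) -> list[RiskLocus]:
    """Greedy P-value + LD clumping of one GWAS into genomic risk loci.

    Significant variants absent from the LD panel are reported and become
    singleton loci.  P ties break by (chr, pos) order.
    """
    if not 0.0 < p_thresh < 1.0:
        raise ValueError(f"p_thresh must be in (0,1), got {p_thresh}")
    t = gwas.table
    sig = t[t["pvalue"] < p_thresh].copy()
    if sig.empty:
        return []
    sig = sig.sort_values(["pvalue", "chr", "pos"]).reset_index(drop=True)

    panel = ancestry_matched_panel(ld_panel, gwas.ancestry, default_ld_label)
    covered = set(panel.variants["rsid"])
    in_panel = sig["rsid"].isin(covered).to_numpy()
    if not in_panel.all():
        logger.warning("define_risk_loci(%s): %d significant variant(s) not "
                       "in LD panel become singleton loci", gwas.phenotype,
                       (~in_panel).sum())
    cov_rsids = sig["rsid"][in_panel].tolist()
    r2 = pairwise_r2(panel, cov_rsids) if cov_rsids else np.empty((0, 0))
    pos_in_cov = {r: i for i, r in enumerate(cov_rsids)}

    loci: list[RiskLocus] = []
    unassigned = np.ones(len(sig), dtype=bool)
    while unassigned.any():
        seed = int(np.flatnonzero(unassigned)[0])  # smallest P (sorted)
        members = [seed]
        unassigned[seed] = False
        srs = sig["rsid"].iloc[seed]
        if srs in pos_in_cov:
            si = pos_in_cov[srs]
            for j in np.flatnonzero(unassigned):
                rj = sig["rsid"].iloc[j]
                if rj in pos_in_cov and r2[si, pos_in_cov[rj]] >= r2_thresh:
                    members.append(int(j))
                    unassigned[j] = False
        loci.append(RiskLocus(
            locus_id=f"{gwas.phenotype}_L{len(loci) + 1}",
            phenotype=gwas.phenotype,
            members=sig["rsid"].iloc[members].tolist(),
            index_rsid=srs,
            min_p=float(sig["pvalue"].iloc[seed]),
            chrom=str(sig["chr"].iloc[seed])))
    return loci


def select_index_snps(loci: list[RiskLocus], mode: str,
                      gwas: GwasSummaryTable) -> SnpSet:
    """One representative variant per locus.

    ``min_p`` keeps the locus seed (smallest P, the "psig" rule);
    ``max_cadd`` keeps the highest-CADD member (the "map" rule), with ties
    broken by smaller P then position, falling back to the min-P member
    (logged) when no member has a CADD score.
    """
    if mode not in ("min_p", "max_cadd"):
        raise ValueError(f"mode must be min_p or max_cadd, got {mode!r}")
    t = gwas.table.set_index("rsid")
    rows = []
    for locus in loci:
        sub = t.loc[locus.members].reset_index()
        if mode == "min_p":
            sub = sub.sort_values(["pvalue", "chr", "pos"])
            pick = sub.iloc[0]
        else:
            with_cadd = sub[sub["cadd"].notna()]
            if with_cadd.empty:
                logger.warning("locus %s: no CADD score on any member; "
                               "falling back to min-P", locus.locus_id)
                pick = sub.sort_values(["pvalue", "chr", "pos"]).iloc[0]
            else:
                pick = with_cadd.sort_values(
                    ["cadd", "pvalue", "chr", "pos"],
                    ascending=[False, True, True, True]).iloc[0]
        row = pick.to_dict()
        row["phenotypes"] = locus.phenotype
        row["locus_id"] = locus.locus_id
        rows.append(row)
    kind = "psig" if mode == "min_p" else "map"
    cols = ["rsid", "chr", "pos", "effect_allele", "other_allele",
            "beta", "se", "pvalue", "cadd", "phenotypes", "locus_id"]
    table = (pd.DataFrame(rows, columns=cols) if rows
             else pd.DataFrame(columns=cols))
    return SnpSet(kind, table)


def build_candidate_pool(snp_sets: list[SnpSet], set_kind: str) -> SnpSet:
    """Union of one set kind across phenotypes; an rsid significant for
    several phenotypes appears once (smallest-P occurrence kept) with all
    source phenotypes recorded."""
    chosen = [s for s in snp_sets if s.kind == set_kind]
    if not chosen or all(len(s) == 0 for s in chosen):
        raise ValueError(f"empty candidate pool for set kind {set_kind!r}")
    merged = pd.concat([s.table for s in chosen], ignore_index=True)
    merged = merged.sort_values(["pvalue", "chr", "pos"])
    out_rows = []
    for rsid, grp in merged.groupby("rsid", sort=False):
        row = grp.iloc[0].copy()
        row["phenotypes"] = ";".join(
            sorted(set(";".join(grp["phenotypes"]).split(";"))))
        out_rows.append(row)
    table = pd.DataFrame(out_rows).sort_values(
        ["chr", "pos"]).reset_index(drop=True)
    return SnpSet(set_kind, table)


# ---------------------------------------------------------------------------
# gene mapping
# ---------------------------------------------------------------------------

def read_gene_annotation(path, format: str = "tsv") -> pd.DataFrame:
    """Gene intervals as (gene, chr, start, end), 1-based inclusive.

    ``tsv`` expects those columns; ``bed`` is 0-based half-open (chrom,
    start, end, name) and is converted; ``gff3`` keeps ``gene`` features and
    takes the Name/gene_name/ID attribute.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"chr": str})
        need = {"gene", "chr", "start", "end"}
        if not need.issubset(df.columns):
            raise ValueError(f"{path}: need columns {sorted(need)}")
        return df[["gene", "chr", "start", "end"]]
    if format == "bed":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2, 3],
                         names=["chr", "start", "end", "gene"],
                         dtype={"chr": str})
        df["start"] = df["start"] + 1  # to 1-based inclusive
        return df[["gene", "chr", "start", "end"]]
    if format == "gff3":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chr", "source", "type", "start", "end",
                                "score", "strand", "phase", "attributes"],
                         dtype={"chr": str})
        df = df[df["type"] == "gene"].copy()

        def _name(attr: str) -> str:
            for key in ("Name", "gene_name", "ID"):
                m = re.search(rf"{key}=([^;]+)", attr)
                if m:
                    return m.group(1)
            return attr
        df["gene"] = df["attributes"].map(_name)
        return df[["gene", "chr", "start", "end"]].reset_index(drop=True)
    raise ValueError(f"unknown annotation format {format!r}")


def map_snps_to_genes(snp_set: SnpSet, annotation: pd.DataFrame,
                      max_distance: int = DEFAULT_MAX_GENE_DISTANCE,
                      ) -> pd.DataFrame:
    """Positional SNP-to-gene mapping.

    A SNP inside a gene interval maps to that gene (all overlapping genes if
    several); otherwise to the nearest gene on its chromosome within
    ``max_distance`` bp.  Equidistant nearest genes are all reported with
    the tie flag set.  Returns (rsid, genes ';'-joined, distance, tie).
    """
    if annotation is None or len(annotation) == 0:
        raise ValueError("empty gene annotation")
    ann_by_chr = {c: g.reset_index(drop=True)
                  for c, g in annotation.groupby("chr")}
    rows = []
    for _, snp in snp_set.table.iterrows():
        genes: list[str] = []
        dist, tie = np.inf, False
        ann = ann_by_chr.get(str(snp["chr"]))
        if ann is not None:
            pos = int(snp["pos"])
            d = np.where(pos < ann["start"], ann["start"] - pos,
                         np.where(pos > ann["end"], pos - ann["end"], 0))
            dmin = int(d.min())
            if dmin <= max_distance:
                hits = ann["gene"][d == dmin].tolist()
                genes = sorted(set(hits))
                dist = dmin
                tie = dmin > 0 and len(genes) > 1
        rows.append((snp["rsid"], ";".join(genes),
                     dist if genes else np.nan, tie))
    return pd.DataFrame(rows, columns=["rsid", "genes", "distance", "tie"])
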