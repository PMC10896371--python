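"""LD clumping against a brute-force oracle, index-SNP selection, candidate
pools, and positional gene mapping."""

import numpy as np
import pandas as pd
import pytest

from demrisk import snp_prioritization as prio
from demrisk.data_io import GwasSummaryTable

from conftest import make_matrix


def _gwas(pvals, rsids=None, chrom=None, pos=None, cadd=None,
          phenotype="AD", ancestry="EA"):
    n = len(pvals)
    return GwasSummaryTable(phenotype, ancestry, pd.DataFrame({
        "chr": chrom if chrom is not None else ["1"] * n,
        "pos": pos if pos is not None else (np.arange(n) + 1) * 1000,
        "rsid": rsids if rsids is not None else [f"rs{i}" for i in range(n)],
        "effect_allele": ["A"] * n, "other_allele": ["G"] * n,
        "beta": [0.1] * n, "se": [0.02] * n, "pvalue": pvals,
        "cadd": cadd if cadd is not None else [5.0] * n}))


def oracle_clump(pvals, r2, p_thresh, r2_thresh, order=None):
    """Independent greedy clumping: repeatedly seed at the smallest P among
    unassigned significant variants and absorb all unassigned significant
    variants with r2 >= threshold to the seed."""
    sig = [i for i in range(len(pvals)) if pvals[i] < p_thresh]
    sig.sort(key=lambda i: (pvals[i], i))
    unassigned = set(sig)
    loci = []
    for seed in sig:
        if seed not in unassigned:
            continue
        members = {seed} | {j for j in unassigned
                            if r2[seed, j] >= r2_thresh}
        unassigned -= members
        loci.append((seed, frozenset(members)))
    return loci


def _panel_with_corr(rng, n_snps, n_samples=300, rho=0.0, block=None):
    """Panel of hard-called dosages with optional AR(1) latent correlation."""
    from scipy.stats import norm
    f = rng.uniform(0.2, 0.8, n_snps)
    z = rng.standard_normal((2, n_samples, n_snps))
    if rho and block:
        for hap in range(2):
            for t in range(1, n_snps):
                if t % block != 0:
                    z[hap, :, t] = rho * z[hap, :, t - 1] + \
                        np.sqrt(1 - rho ** 2) * z[hap, :, t]
    dos = ((z[0] < norm.ppf(f)).astype(float)
           + (z[1] < norm.ppf(f)).astype(float))
    return make_matrix(dos, populations=None)


class TestDefineRiskLoci:
    def test_no_significant_variants_gives_empty_list(self):
        gwas = _gwas([0.5, 1e-4, 0.01])
        panel = _panel_with_corr(np.random.default_rng(0), 3)
        assert prio.define_risk_loci(gwas, panel) == []

    def test_p_just_above_threshold_excluded(self):
        gwas = _gwas([6e-8, 1e-9])
        panel = _panel_with_corr(np.random.default_rng(0), 2)
        loci = prio.define_risk_loci(gwas, panel)
        members = {m for l in loci for m in l.members}
        assert "rs0" not in members and "rs1" in members

    def test_two_correlated_pairs_give_two_loci(self):
        """Pairs (A,B) and (C,D) correlated within but not across pairs
        clump into two loci indexed by the smaller-P member."""
        rng = np.random.default_rng(5)
        a = rng.integers(0, 3, 500).astype(float)
        c = rng.integers(0, 3, 500).astype(float)
        flip = rng.random(500) < 0.15
        b = np.where(flip, rng.integers(0, 3, 500), a)
        d = np.where(flip, rng.integers(0, 3, 500), c)
        panel = make_matrix(np.column_stack([a, b, c, d]))
        r2 = prio.pairwise_r2(panel, ["rs0", "rs1", "rs2", "rs3"])
        assert r2[0, 1] > 0.5 and r2[0, 2] < 0.2
        gwas = _gwas([1e-9, 1e-8, 5e-10, 1e-8])
        loci = prio.define_risk_loci(gwas, panel, r2_thresh=0.2)
        got = {frozenset(l.members) for l in loci}
        assert got == {frozenset({"rs0", "rs1"}), frozenset({"rs2", "rs3"})}
        assert {l.index_rsid for l in loci} == {"rs0", "rs2"}

    @pytest.mark.parametrize("r2_thresh", [0.2, 0.1])
    def test_matches_bruteforce_oracle_on_random_instances(self, r2_thresh):
        rng = np.random.default_rng(42)
        for _ in range(40):
            n = int(rng.integers(5, 25))
            panel = _panel_with_corr(rng, n, 200, rho=0.7, block=4)
            rsids = [f"rs{i}" for i in range(n)]
            r2 = prio.pairwise_r2(panel, rsids)
            pvals = 10 ** rng.uniform(-12, -4, n)
            gwas = _gwas(pvals)
            loci = prio.define_risk_loci(gwas, panel, r2_thresh=r2_thresh)
            got = {frozenset(l.members) for l in loci}
            expect = {frozenset(rsids[j] for j in mem)
                      for _, mem in oracle_clump(pvals, r2, 5e-8, r2_thresh)}
            assert got == expect

    def test_threshold_monotonicity_and_partition(self):
        """Loci always partition the significant set, and a lower
        recruitment threshold can only reduce the locus count."""
        rng = np.random.default_rng(11)
        panel = _panel_with_corr(rng, 20, 200, rho=0.8, block=5)
        pvals = 10 ** rng.uniform(-12, -6, 20)
        gwas = _gwas(pvals)
        coarse = prio.define_risk_loci(gwas, panel, r2_thresh=0.2)
        fine = prio.define_risk_loci(gwas, panel, r2_thresh=0.1)
        assert len(fine) <= len(coarse)
        n_sig = int((pvals < 5e-8).sum())
        for loci in (coarse, fine):
            members = [m for l in loci for m in l.members]
            assert len(members) == len(set(members)) == n_sig

    def test_invalid_p_threshold_rejected(self):
        gwas = _gwas([0.5])
        panel = _panel_with_corr(np.random.default_rng(0), 1)
        with pytest.raises(ValueError, match="p_thresh"):
            prio.define_risk_loci(gwas, panel, p_thresh=2.0)

    def test_cross_chromosome_variants_never_clump(self):
        dup = np.tile(np.random.default_rng(2).integers(0, 3, 300), (2, 1)).T
        panel = make_matrix(dup.astype(float), chrom=["1", "2"])
        gwas = _gwas([1e-9, 1e-9], chrom=["1", "2"])
        loci = prio.define_risk_loci(gwas, panel)
        assert len(loci) == 2


class TestSelectIndexSnps:
    def test_singleton_locus_selected_in_both_modes(self):
        gwas = _gwas([1e-9])
        locus = prio.RiskLocus("L1", "AD", ["rs0"], "rs0", 1e-9, "1")
        for mode in ("min_p", "max_cadd"):
            s = prio.select_index_snps([locus], mode, gwas)
            assert s.rsids == ["rs0"]

    def test_psig_and_map_pick_different_members(self):
        gwas = _gwas([1e-9, 1e-8], cadd=[5.0, 20.0])
        locus = prio.RiskLocus("L1", "AD", ["rs0", "rs1"], "rs0", 1e-9, "1")
        assert prio.select_index_snps([locus], "min_p", gwas).rsids == ["rs0"]
        assert prio.select_index_snps([locus], "max_cadd",
                                      gwas).rsids == ["rs1"]

    def test_all_missing_cadd_falls_back_to_min_p(self, caplog):
        gwas = _gwas([1e-9, 1e-8], cadd=[np.nan, np.nan])
        locus = prio.RiskLocus("L1", "AD", ["rs0", "rs1"], "rs0", 1e-9, "1")
        with caplog.at_level("WARNING"):
            s = prio.select_index_snps([locus], "max_cadd", gwas)
        assert s.rsids == ["rs0"]

    def test_random_loci_match_argmin_argmax_scan(self):
        rng = np.random.default_rng(7)
        n = 300
        pv = 10 ** rng.uniform(-12, -8, n)
        cadd = rng.gamma(2, 4, n)
        gwas = _gwas(pv, cadd=cadd)
        rsids = gwas.table["rsid"].tolist()
        loci = []
        start = 0
        k = 0
        while start < n:
            size = int(rng.integers(1, 7))
            members = rsids[start:start + size]
            loci.append(prio.RiskLocus(f"L{k}", "AD", members, members[0],
                                       min(pv[start:start + size]), "1"))
            start += size
            k += 1
        psig = prio.select_index_snps(loci, "min_p", gwas)
        mapset = prio.select_index_snps(loci, "max_cadd", gwas)
        t = gwas.table.set_index("rsid")
        for locus, chosen_p, chosen_c in zip(loci, psig.rsids, mapset.rsids):
            sub = t.loc[locus.members]
            assert sub.loc[chosen_p, "pvalue"] == sub["pvalue"].min()
            assert sub.loc[chosen_c, "cadd"] == sub["cadd"].max()


class TestCandidatePool:
    def _set(self, rsids, pvals, pheno):
        rows = pd.DataFrame({
            "rsid": rsids, "chr": "1",
            "pos": np.arange(len(rsids)) + 1, "effect_allele": "A",
            "other_allele": "G", "beta": 0.1, "se": 0.02, "pvalue": pvals,
            "cadd": 5.0, "phenotypes": pheno,
            "locus_id": [f"{pheno}_L{i}" for i in range(len(rsids))]})
        return prio.SnpSet("psig", rows)

    def test_single_phenotype_pool_is_identity(self):
        s = self._set(["rs1", "rs2"], [1e-9, 1e-10], "AD")
        pool = prio.build_candidate_pool([s], "psig")
        assert sorted(pool.rsids) == ["rs1", "rs2"]

    def test_shared_rsid_appears_once_with_both_phenotypes(self):
        a = self._set(["rs1"], [1e-9], "AD")
        b = self._set(["rs1"], [1e-11], "LBD")
        pool = prio.build_candidate_pool([a, b], "psig")
        assert len(pool) == 1
        assert pool.table["phenotypes"].iloc[0] == "AD;LBD"
        assert pool.table["pvalue"].iloc[0] == 1e-11

    def test_empty_union_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            prio.build_candidate_pool([], "psig")

    def test_stringent_r2_gives_more_independent_smaller_pool(
            self, small_study):
        """The stringent sensitivity setting (recruit partners at r^2 >=
        0.1 instead of 0.2) absorbs more partners per clump, so the index
        pool shrinks or stays the same — the selected SNPs are more
        independent."""
        gwas = small_study.gwas_tables[0]
        panel = small_study.reference_panel
        sizes = {}
        for thresh in (0.2, 0.1):
            loci = prio.define_risk_loci(gwas, panel, r2_thresh=thresh)
            sizes[thresh] = len(prio.build_candidate_pool(
                [prio.select_index_snps(loci, "min_p", gwas)], "psig"))
        assert sizes[0.1] <= sizes[0.2]


class TestGeneMapping:
    ANN = pd.DataFrame({
        "gene": ["APOE", "TOMM40", "FAR"],
        "chr": ["19", "19", "19"],
        "start": [44905791, 44891220, 45500000],
        "end": [44909393, 44903689, 45600000]})

    def _snpset(self, rsids, chrom, pos):
        return prio.SnpSet("map", pd.DataFrame({
            "rsid": rsids, "chr": chrom, "pos": pos,
            "effect_allele": "C", "other_allele": "T", "beta": 0.1,
            "se": 0.02, "pvalue": 1e-9, "cadd": 20.0,
            "phenotypes": "AD", "locus_id": "L1"}))

    def test_apoe_variant_maps_inside_apoe(self):
        s = self._snpset(["rs429358"], ["19"], [44908684])
        out = prio.map_snps_to_genes(s, self.ANN)
        assert out["genes"].iloc[0] == "APOE"
        assert out["distance"].iloc[0] == 0

    def test_equidistant_snp_reports_both_genes_with_tie(self):
        ann = pd.DataFrame({"gene": ["L", "R"], "chr": ["1", "1"],
                            "start": [100, 500], "end": [200, 600]})
        s = self._snpset(["rsX"], ["1"], [350])
        out = prio.map_snps_to_genes(s, ann, max_distance=1000)
        assert out["genes"].iloc[0] == "L;R" and bool(out["tie"].iloc[0])

    def test_far_snp_beyond_max_distance_unmapped(self):
        s = self._snpset(["rsY"], ["19"], [47000000])
        out = prio.map_snps_to_genes(s, self.ANN, max_distance=250_000)
        assert out["genes"].iloc[0] == ""

    def test_empty_annotation_rejected(self):
        s = self._snpset(["rs1"], ["1"], [100])
        with pytest.raises(ValueError, match="empty"):
            prio.map_snps_to_genes(s, pd.DataFrame())

    def test_random_snps_match_bruteforce_nearest_scan(self):
        rng = np.random.default_rng(9)
        genes = pd.DataFrame({
            "gene": [f"G{i}" for i in range(30)],
            "chr": rng.choice(["1", "2"], 30),
            "start": rng.integers(1, 10_000_000, 30)})
        genes["end"] = genes["start"] + rng.integers(1000, 100_000, 30)
        pos = rng.integers(1, 10_000_000, 50)
        chrom = rng.choice(["1", "2"], 50)
        s = self._snpset([f"rs{i}" for i in range(50)], chrom, pos)
        out = prio.map_snps_to_genes(s, genes, max_distance=10_000_000)
        for i in range(50):
            dists = {}
            for _, g in genes[genes["chr"] == chrom[i]].iterrows():
                if g["start"] <= pos[i] <= g["end"]:
                    d = 0
                elif pos[i] < g["start"]:
                    d = g["start"] - pos[i]
                else:
                    d = pos[i] - g["end"]
                dists[g["gene"]] = d
            expect = sorted(g for g, d in dists.items()
                            if d == min(dists.values()))
            assert out["genes"].iloc[i] == ";".join(expect)


class TestBedGff:
    def test_bed_interval_converted_to_one_based(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("1\t99\t200\tGENEA\n")
        ann = prio.read_gene_annotation(p, format="bed")
        assert ann.loc[0, "start"] == 100 and ann.loc[0, "end"] == 200

    def test_gff3_gene_features_parsed(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text("##gff-version 3\n"
                     "1\tsrc\tgene\t100\t200\t.\t+\t.\tID=g1;Name=GENEA\n"
                     "1\tsrc\texon\t100\t150\t.\t+\t.\tID=e1\n")
        ann = prio.read_gene_annotation(p, format="gff3")
        assert ann["gene"].tolist() == ["GENEA"]
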