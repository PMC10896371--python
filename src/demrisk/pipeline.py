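"""End-to-end pipeline orchestration, stratified by genetic-ancestry group.

Stage order per group: genotype QC -> ancestry inference -> cohort
phenotyping -> SNP prioritization -> PRS/APOE scoring -> permutation
evaluation of the four model families -> pairwise comparisons -> feature
importance -> positional gene mapping -> gene-set enrichment.  Stage
outputs are plain TSV/JSON files so any stage can be re-run independently;
a manifest records the seed, config hash, and package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, ancestry, cohort, enrichment, evaluation
from . import genetic_scores as scores
from . import modeling, snp_prioritization as prio, synthetic_data as synth
from .data_io import write_dosage_tsv, write_gwas_summary, \
    write_patient_records, write_truth_json

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = 0
    n_iterations: int = 1000
    control_ratio: int = 3
    p_thresh: float = 5e-8
    r2_thresh: float = 0.2
    n_global_pcs: int = 10
    n_group_pcs: int = 5
    gia_radius_sd: float = 6.0
    cv_folds: int = 5
    groups: list[str] | None = None      # None = every assignable group
    families: tuple[str, ...] = modeling.FAMILIES
    enet_grid: modeling.ElasticNetGrid = field(
        default_factory=lambda: modeling.SMALL_GRID)
    max_gene_distance: int = 250_000
    sim: synth.SimulationConfig | None = None   # None = default scenario

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "enet_grid" in raw:
            raw["enet_grid"] = modeling.ElasticNetGrid(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in raw["enet_grid"].items()})
        if "sim" in raw and raw["sim"] is not None:
            raw["sim"] = synth.SimulationConfig(**raw["sim"])
        if "families" in raw:
            raw["families"] = tuple(raw["families"])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True,
                          default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def _model_age_covariates(records_by_id, cases: dict[str, float],
                          ids: list[str]) -> np.ndarray:
    return np.array([cohort.model_age(records_by_id[i], cases.get(i))
                     for i in ids])


def build_group_inputs(study: synth.SimulatedStudy,
                       profile: ancestry.AncestryProfile,
                       cases: dict[str, float], pool: list[str],
                       group: str, config: PipelineConfig):
    """Assemble per-group modeling inputs: cases/pool restricted to the
    group, covariate frame, and the four feature frames."""
    lab = np.asarray(profile.gia_labels)
    in_group = {s for s, g in zip(profile.samples, lab) if g == group}
    g_cases = {k: v for k, v in cases.items() if k in in_group}
    g_pool = [p for p in pool if p in in_group]
    ids = sorted(in_group)
    geno = study.cohort_genotypes
    sample_pos = {s: i for i, s in enumerate(geno.samples)}
    rows = [sample_pos[s] for s in ids]
    sub = geno.take_samples(np.array(rows))

    records_by_id = {r.patient_id: r for r in study.patient_records}
    age = _model_age_covariates(records_by_id, g_cases, ids)
    sex = np.array([1.0 if records_by_id[i].sex == "male" else 0.0
                    for i in ids])
    prof_pos = {s: i for i, s in enumerate(profile.samples)}
    pcs = profile.group_pcs[[prof_pos[i] for i in ids]]
    cov = pd.DataFrame({"age": age, "sex": sex}, index=ids)
    for j in range(pcs.shape[1]):
        cov[f"PC{j + 1}"] = pcs[:, j]
    if cov.filter(like="PC").isna().any().any():
        cov = cov.drop(columns=[c for c in cov if c.startswith("PC")])
    return g_cases, g_pool, ids, sub, cov


def build_feature_frames(study: synth.SimulatedStudy, group_geno,
                         ids: list[str], config: PipelineConfig,
                         results_dir: Path | None = None) -> dict:
    """SNP prioritization + scoring for one group's genotype slice.

    Returns feature frames keyed by family plus the map-pool SnpSet for
    downstream gene mapping.
    """
    ref = study.reference_panel
    loci_all, snp_sets = [], []
    for gwas in study.gwas_tables:
        loci = prio.define_risk_loci(
            gwas, ref, p_thresh=config.p_thresh, r2_thresh=config.r2_thresh,
            default_ld_label=study.config.populations[0].label)
        loci_all += loci
        if loci:
            snp_sets.append(prio.select_index_snps(loci, "min_p", gwas))
            snp_sets.append(prio.select_index_snps(loci, "max_cadd", gwas))
    psig_pool = prio.build_candidate_pool(snp_sets, "psig")
    map_pool = prio.build_candidate_pool(snp_sets, "map")

    # reference standardization population: the first configured population
    ref_label = study.config.populations[0].label
    ref_idx = np.flatnonzero(np.asarray(ref.populations) == ref_label)
    ref_sub = ref.take_samples(ref_idx)

    prs_cols = {}
    per_pheno = {}
    for gwas in study.gwas_tables:
        for kind, pool_set in (("psig", psig_pool), ("map", map_pool)):
            sub_tab = pool_set.table[pool_set.table["phenotypes"].apply(
                lambda s: gwas.phenotype in s.split(";"))]
            if sub_tab.empty:
                continue
            one = prio.SnpSet(kind, sub_tab.reset_index(drop=True))
            try:
                raw, _ = scores.compute_prs(group_geno, one)
                ref_raw, _ = scores.compute_prs(ref_sub, one)
            except ValueError:
                continue
            std = scores.standardize_scores(raw, ref_raw)
            name = f"PRS_{gwas.phenotype}_{kind}"
            prs_cols[name] = std
            per_pheno.setdefault(gwas.phenotype, {})[kind] = name

    apoe = scores.apoe_e4_count(group_geno)
    features = {
        "apoe": pd.DataFrame({"apoe_e4_count": apoe.counts}, index=ids)}
    if prs_cols:
        prs_frame = pd.DataFrame(prs_cols, index=ids)
        first = sorted(prs_cols)[0]
        ad_first = per_pheno.get("AD", {}).get(
            "psig", per_pheno.get("AD", {}).get("map", first))
        features["single_prs"] = prs_frame[[ad_first]]
        features["multi_prs"] = prs_frame
    snp_idx = group_geno.variant_index(map_pool.rsids)
    dos = group_geno.dosages[:, snp_idx]
    dos = np.where(np.isnan(dos), np.nanmean(dos, axis=0, keepdims=True),
                   dos)
    features["enet_snp"] = pd.DataFrame(dos, index=ids,
                                        columns=map_pool.rsids)
    if results_dir is not None:
        pd.DataFrame([(l.locus_id, l.phenotype, l.index_rsid, l.min_p,
                       ";".join(l.members)) for l in loci_all],
                     columns=["locus_id", "phenotype", "index_rsid",
                              "min_p", "members"]) \
            .to_csv(results_dir / "risk_loci.tsv", sep="\t", index=False)
        map_pool.table.to_csv(results_dir / "candidate_pool_map.tsv",
                              sep="\t", index=False)
        psig_pool.table.to_csv(results_dir / "candidate_pool_psig.tsv",
                               sep="\t", index=False)
    return {"features": features, "map_pool": map_pool,
            "psig_pool": psig_pool}


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the full synthetic study end to end; returns the report bundle
    (also written under ``outdir``)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim_cfg = config.sim or synth.default_config(seed=config.seed)
    study = synth.simulate_study(sim_cfg)

    write_dosage_tsv(study.cohort_genotypes, out / "cohort_dosages.tsv")
    for gwas in study.gwas_tables:
        write_gwas_summary(gwas, out / f"gwas_{gwas.phenotype}.tsv")
    write_patient_records(study.patient_records, out / "encounters.tsv")
    write_truth_json(study.truth, out / "truth.json")

    profile = ancestry.profile_cohort(
        study.cohort_genotypes, study.reference_panel,
        n_global=config.n_global_pcs, n_group=config.n_group_pcs,
        radius_sd=config.gia_radius_sd)
    profile.to_frame().to_csv(out / "ancestry.tsv", sep="\t", index=False)

    cases, pool, exclusions = cohort.build_cohort(study.patient_records)
    pd.DataFrame([(k, ";".join(v)) for k, v in exclusions.items()],
                 columns=["rule", "patient_ids"]) \
        .to_csv(out / "cohort_exclusions.tsv", sep="\t", index=False)

    groups = config.groups or sorted(
        set(profile.gia_labels) - {ancestry.UNASSIGNED})
    bundle = {"groups": {}, "seed": config.seed}
    for group in groups:
        gdir = out / f"group_{group}"
        gdir.mkdir(exist_ok=True)
        g_cases, g_pool, ids, g_geno, cov = build_group_inputs(
            study, profile, cases, pool, group, config)
        if len(g_cases) < config.cv_folds:
            logger.warning("group %s skipped: %d case(s) < %d folds",
                           group, len(g_cases), config.cv_folds)
            bundle["groups"][group] = {"skipped": "limited case count",
                                       "n_cases": len(g_cases)}
            continue
        if len(g_pool) < config.control_ratio * len(g_cases):
            logger.warning("group %s skipped: control pool %d too small",
                           group, len(g_pool))
            bundle["groups"][group] = {"skipped": "insufficient controls",
                                       "n_cases": len(g_cases)}
            continue
        built = build_feature_frames(study, g_geno, ids, config,
                                     results_dir=gdir)
        specs = [evaluation.ModelSpec(
                    name=fam, family=fam, features=built["features"][fam],
                    enet_grid=config.enet_grid, cv_folds=config.cv_folds)
                 for fam in config.families
                 if fam in built["features"]]
        perm = evaluation.run_permutation(
            g_cases, g_pool, specs, cov, n_iter=config.n_iterations,
            base_seed=config.seed, ratio=config.control_ratio)
        perm.summary().to_csv(gdir / "metric_summary.tsv", sep="\t",
                              index=False)
        perm.draws_long().to_csv(gdir / "metric_draws.tsv", sep="\t",
                                 index=False)

        comparisons = []
        if "enet_snp" in perm.models:
            for other in ("apoe", "single_prs", "multi_prs"):
                if other not in perm.models:
                    continue
                for metric in ("auprc", "auroc"):
                    cmp_ = evaluation.compare_models(
                        perm.models[other], perm.models["enet_snp"], metric)
                    comparisons.append(
                        {"model_1": other, "model_2": "enet_snp",
                         "metric": metric, "count": cmp_.count,
                         "n": cmp_.n, "p": cmp_.display,
                         "direction": cmp_.direction})
        pd.DataFrame(comparisons).to_csv(gdir / "comparisons.tsv",
                                         sep="\t", index=False)

        # importance + gene mapping + enrichment on the seed resample
        group_report = {
            "n_cases": len(g_cases), "n_pool": len(g_pool),
            "summary": perm.summary().to_dict(orient="records"),
            "comparisons": comparisons}
        if "enet_snp" in built["features"]:
            sample = cohort.sample_case_control(
                g_cases, g_pool, ratio=config.control_ratio,
                seed=config.seed)
            y = sample.labels()
            scov = cov.loc[sample.ids]
            pc_cols = [c for c in scov if c.startswith("PC")]
            om = modeling.fit_offset_model(
                y, scov["age"].to_numpy(), scov["sex"].to_numpy(),
                scov[pc_cols].to_numpy() if pc_cols else None)
            model, _ = modeling.fit_genetic_model(
                built["features"]["enet_snp"].loc[sample.ids], y,
                om.offsets, "enet_snp", cv_folds=config.cv_folds,
                enet_grid=config.enet_grid, seed=config.seed)
            imp = modeling.feature_importance(
                model, built["features"]["enet_snp"].loc[sample.ids])
            imp.rename("importance").to_csv(gdir / "importance.tsv",
                                            sep="\t")
            (gdir / "model_enet_snp.json").write_text(
                json.dumps(model.to_dict(), indent=2))

            selected = prio.SnpSet("map", built["map_pool"].table[
                built["map_pool"].table["rsid"].isin(imp.index)]
                .reset_index(drop=True))
            ann = synth.synthetic_gene_annotation(study.config)
            mapping = prio.map_snps_to_genes(
                selected, ann, max_distance=config.max_gene_distance)
            mapping.to_csv(gdir / "gene_mapping.tsv", sep="\t", index=False)
            mapped_genes = sorted({g for gs in mapping["genes"]
                                   for g in gs.split(";") if g})
            gene_sets = synth.synthetic_gene_sets(study.config)
            enr = enrichment.hypergeom_enrich(
                mapped_genes, gene_sets, ann["gene"].tolist())
            enrichment.results_to_frame(enr).to_csv(
                gdir / "enrichment.tsv", sep="\t", index=False)
            kept = enrichment.filter_enriched(enr)
            group_report["mapped_genes"] = mapped_genes
            group_report["enriched_sets"] = [r.gene_set for r in kept]
        bundle["groups"][group] = group_report

    manifest = {"version": __version__, "seed": config.seed,
                "config_hash": config.config_hash(),
                "n_iterations": config.n_iterations,
                "groups_run": list(bundle["groups"])}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    bundle["manifest"] = manifest
    return bundle
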