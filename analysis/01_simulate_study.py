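#!/usr/bin/env python
"""Generate the two synthetic studies the analyses run on.

Writes the default three-ancestry study and the ancestry-heterogeneous
study (per-locus attenuated EA effects + AA-specific loci) as plain files
under results/data/: dosage matrices, a VCF, GWAS summary tables, EHR
encounter records, and the ground-truth JSON.
"""

import argparse
from pathlib import Path

from demrisk import data_io, synthetic_data as synth


def write_study(study, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    data_io.write_dosage_tsv(study.reference_panel,
                             outdir / "reference_dosages.tsv")
    data_io.write_dosage_tsv(study.cohort_genotypes,
                             outdir / "cohort_dosages.tsv")
    data_io.write_vcf(study.cohort_genotypes, outdir / "cohort.vcf")
    for gwas in study.gwas_tables:
        data_io.write_gwas_summary(gwas, outdir / f"gwas_{gwas.phenotype}.tsv")
    data_io.write_patient_records(study.patient_records,
                                  outdir / "encounters.tsv")
    data_io.write_truth_json(study.truth, outdir / "truth.json")


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    args = ap.parse_args()

    default = synth.simulate_study(synth.default_config(seed=args.seed))
    write_study(default, args.out / "default")
    hetero = synth.simulate_study(synth.heterogeneous_config(seed=args.seed))
    write_study(hetero, args.out / "heterogeneous")

    n_cases = sum(default.truth["case_labels"].values())
    print(f"default study: {default.cohort_genotypes.n_samples} patients, "
          f"{default.cohort_genotypes.n_variants} SNPs, {n_cases} true cases")
    n_cases = sum(hetero.truth["case_labels"].values())
    print(f"heterogeneous study: {hetero.cohort_genotypes.n_samples} "
          f"patients, {n_cases} true cases; GWAS tables: "
          f"{[g.phenotype for g in hetero.gwas_tables]}")


if __name__ == "__main__":
    main()
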