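import numpy as np
import pandas as pd
import pytest

from demrisk import synthetic_data as synth
from demrisk.data_io import GenotypeDosageMatrix


@pytest.fixture(scope="session")
def small_config():
    """A compact two-population study used across module tests."""
    return synth.SimulationConfig(
        seed=7,
        populations=[synth.PopulationSpec("EA", 120, 200, 0.02),
                     synth.PopulationSpec("AA", 120, 200, 0.12)],
        n_snps=60, ld_block_length=6, within_block_corr=0.7,
        causal_plan=[synth.CausalEffect(3, "AD", 0.5),
                     synth.CausalEffect(21, "AD", 0.4),
                     synth.CausalEffect(40, "LBD", 0.5)],
        gwas_n=5e4, apoe_e4_effect=0.6)


@pytest.fixture(scope="session")
def small_study(small_config):
    return synth.simulate_study(small_config)


def make_matrix(dosages, rsids=None, chrom=None, pos=None, effect=None,
                other=None, samples=None, populations=None, imput_r2=None):
    """Hand-built GenotypeDosageMatrix for fixture tests."""
    dosages = np.asarray(dosages, dtype=float)
    n, p = dosages.shape
    variants = pd.DataFrame({
        "chr": chrom if chrom is not None else ["1"] * p,
        "pos": pos if pos is not None else (np.arange(p) + 1) * 1000,
        "rsid": rsids if rsids is not None else [f"rs{i}" for i in range(p)],
        "effect_allele": effect if effect is not None else ["A"] * p,
        "other_allele": other if other is not None else ["G"] * p,
    })
    if imput_r2 is not None:
        variants["imputation_r2"] = imput_r2
    return GenotypeDosageMatrix(
        samples if samples is not None else [f"s{i}" for i in range(n)],
        variants, dosages, populations)
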