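import numpy as np
import pandas as pd
import pytest

from mrphewas import InstrumentSet, SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_instruments() -> InstrumentSet:
    """Five SNPs with mixed signs for hand-checked score arithmetic."""
    return InstrumentSet(pd.DataFrame({
        "snp": ["rs1", "rs2", "rs3", "rs4", "rs5"],
        "chrom": ["1", "2", "3", "4", "5"],
        "pos": [1_000_000] * 5,
        "effect_allele": ["A", "T", "G", "C", "A"],
        "other_allele": ["G", "C", "A", "T", "C"],
        "beta": [0.5, -0.3, 0.2, -0.1, 0.4],
        "se": [0.05, 0.03, 0.02, 0.01, 0.04],
        "pval": [1e-10, 1e-9, 1e-8, 1e-12, 1e-11],
        "eaf": [0.3, 0.5, 0.2, 0.4, 0.25],
        "annotation": ["DDR", "non-DDR", "DDR", "non-DDR", "unknown"],
    }))


@pytest.fixture(scope="session")
def small_genotypes() -> pd.DataFrame:
    """Four individuals x five SNPs, complete dosages."""
    return pd.DataFrame(
        [[0, 1, 2, 0, 1],
         [1, 2, 0, 1, 0],
         [2, 0, 1, 2, 2],
         [1, 1, 1, 1, 1]],
        columns=["rs1", "rs2", "rs3", "rs4", "rs5"], dtype=float)


@pytest.fixture(scope="session")
def seeded_cohort():
    """A moderately sized cohort with planted continuous + binary effects."""
    cfg = SimConfig(
        n_individuals=4000, n_snps=60, seed=42, target_r2=0.073,
        trait_spec=[
            dict(field_id="bmd", trait_type="continuous", effect=-0.05,
                 category="bone"),
            dict(field_id="null_cont", trait_type="continuous", effect=0.0,
                 category="null"),
            dict(field_id="cancer", trait_type="binary", effect=0.04,
                 prevalence=0.3, category="cancer"),
            dict(field_id="grade", trait_type="ordered_categorical",
                 effect=0.1, category="bone"),
            dict(field_id="diet", trait_type="unordered_categorical",
                 effect=0.0, category="diet"),
        ])
    cohort, instruments, truth = simulate_cohort(cfg)
    return cfg, cohort, instruments, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
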