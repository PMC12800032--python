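import numpy as np
import pandas as pd
import pytest

import ctcsig as cs


@pytest.fixture(scope="session")
def default_config():
    return cs.GeneratorConfig(seed=7)


@pytest.fixture(scope="session")
def small_config():
    """Reduced cohort for fast unit tests (keeps panel ratios, shrinks n)."""
    return cs.GeneratorConfig(
        seed=7, n_ctc_genes=20, n_bc_genes=6, n_emt_genes=4,
        n_tumor=80, n_normal=20, n_driver_genes=6,
        genome_length=60_000_000, n_chromosomes=3, n_ctc_regions=8,
        n_cn_tumor=60, n_cn_normals=12, n_cn_driver_bins=3,
        n_survival=120, n_fish_patients=10, cells_per_core=60,
    )


@pytest.fixture(scope="session")
def strong_signal_config():
    """Study condition for recovery properties: |effect|/noise >= 2."""
    return cs.GeneratorConfig(seed=7, driver_effect_low=1.0,
                              driver_effect_high=2.0, score_noise_sd=1.25)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return cs.generate_expression_cohort(small_config)


@pytest.fixture(scope="session")
def small_norm(small_cohort):
    return cs.hk_normalize(small_cohort)


@pytest.fixture(scope="session")
def small_cn(small_config):
    return cs.generate_cn_cohort(small_config)


@pytest.fixture(scope="session")
def small_survival(small_config):
    return cs.generate_survival_cohort(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_fish_core(counts_rows, core_id="C1", patient_id="P1", tissue="tumor"):
    """Build a FishCore from a list of per-cell count dicts."""
    cols = list(cs.FISH_PROBES) + [cs.FISH_CONTROL]
    df = pd.DataFrame(counts_rows)[cols]
    df.index = [f"{core_id}_c{i}" for i in range(len(df))]
    return cs.FishCore(counts=df, core_id=core_id, patient_id=patient_id,
                       tissue=tissue)
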