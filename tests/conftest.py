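import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_sim():
    """One small but fully structured population shared by read-only tests."""
    from crossgen_gs.synthetic_data import SimConfig, simulate_population

    cfg = SimConfig(
        n_founders=60,
        n_families_phenotyped=20,
        progeny_per_family_per_trial=3,
        n_blocks_per_trial=5,
        n_markers=400,
        n_qtl=80,
        target_h2=0.5,
        seed=42,
    )
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def small_kernel(small_sim):
    from crossgen_gs.relationships import blend, build_G

    return blend(build_G(small_sim.genotypes), 0.98)


@pytest.fixture(scope="session")
def small_adjusted(small_sim, small_kernel):
    from crossgen_gs.experiments import adjusted_whole_core

    return adjusted_whole_core(small_sim, kernel=small_kernel)


@pytest.fixture(scope="session")
def small_cohorts(small_sim):
    d = small_sim.design
    return pd.Series(d["cohort"].to_numpy(), index=d["id"].to_numpy())


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
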