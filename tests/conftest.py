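import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from arrayqc import simcohort


@pytest.fixture(scope="session")
def small_manifest():
    """Compact manifest: 400 autosomal (all categories), 60 X, 30 Y, 34 MT, 6 PAR."""
    return simcohort.default_manifest(n_autosomal=400, n_x=60, n_y=30, n_mt=34, n_par=6)


@pytest.fixture(scope="session")
def components_small(small_manifest):
    comps = simcohort.default_components(fst=0.15)
    return simcohort.simulate_frequencies(len(small_manifest.autosomal_ids()), comps, seed=11)


@pytest.fixture(scope="session")
def small_cohort(components_small, small_manifest):
    """8 founders per population (72 total) plus one trio family, two platforms."""
    pops = simcohort.default_populations(components_small)
    cohort = simcohort.simulate_individuals(
        components_small, pops, n_per_pop=8, seed=21, manifest=small_manifest
    )
    father = "Norwegian_0000"
    mother = "Norwegian_0001"
    simcohort.add_family(cohort, father, mother, n_children=2, seed=22)
    simcohort.genotype_on_platform(cohort, "alpha", error_rate=0.002, missing_rate=0.01, seed=31)
    simcohort.genotype_on_platform(cohort, "beta", error_rate=0.002, missing_rate=0.01, seed=32)
    return cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
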