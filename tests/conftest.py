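import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sexscan import simdata

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def xy_sim():
    """Small XY genome with one 80-kb sex-determining region, no noise."""
    layout = simdata.GenomeLayout(
        chromosomes=(("chr1", 500_000),),
        sd_architecture=simdata.SDArchitecture.XY,
        sd_regions=(("chr1", 200_000, 280_000),),
    )
    pop = simdata.PopulationSpec(
        seed=11,
        n_males=20,
        n_females=20,
        snp_density=0.004,
        genotype_error_rate=0.0,
        missing_rate=0.0,
    )
    matrix, sheet, truth = simdata.simulate_genotypes(layout, pop)
    return matrix, sheet, truth


@pytest.fixture(scope="session")
def null_sim():
    """No sex-linked variation; moderate error and missingness."""
    layout = simdata.GenomeLayout(
        chromosomes=(("chr1", 500_000),),
        sd_architecture=simdata.SDArchitecture.NULL,
    )
    pop = simdata.PopulationSpec(
        seed=13,
        n_males=20,
        n_females=20,
        snp_density=0.004,
        genotype_error_rate=0.005,
        missing_rate=0.02,
    )
    matrix, sheet, truth = simdata.simulate_genotypes(layout, pop)
    return matrix, sheet, truth


@pytest.fixture(scope="session")
def paralog_pair():
    return simdata.make_paralog_pair(simdata.ParalogSpec(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
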