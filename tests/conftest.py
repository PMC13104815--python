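import pytest

import clonetracer as ct


@pytest.fixture(scope="session")
def pattern():
    return ct.BarcodePattern()


def run_simulation(config, pattern):
    """Library -> transduction -> growth/seeding -> reads, returning all stages."""
    library = ct.simulate_library(pattern, config.library_size, config.seed)
    founders = ct.simulate_transduction(
        config.n_cells, library, config.moi, config.seed
    )
    populations = ct.simulate_growth_and_seeding(founders, config, library)
    sim = ct.simulate_reads(populations, config, pattern)
    return library, founders, populations, sim


@pytest.fixture(scope="session")
def clean_run(pattern):
    """Error-free tagged simulation spanning a primary and two bottlenecked
    metastatic sites; reused wherever exact truth-table agreement is needed."""
    config = ct.SimulationConfig(
        n_cells=600,
        moi=0.3,
        seed=42,
        sampled_cells_per_site=120,
        molecules_per_cell=8.0,
        reads_per_molecule=2.0,
        bottleneck_sizes={"lung": 250, "liver": 250},
        growth_params={"concentration": 0.3, "population_size": 4000},
    )
    library, founders, populations, sim = run_simulation(config, pattern)
    return dict(
        config=config,
        library=library,
        founders=founders,
        populations=populations,
        sim=sim,
    )


@pytest.fixture(scope="session")
def clean_hits(clean_run, pattern):
    return ct.extract_hits(clean_run["sim"].reads, pattern, max_mismatches=2)
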