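import pytest

from quartet_hub.simulate import (
    SimulationConfig,
    simulate_chip_replicates,
    simulate_counts,
    simulate_genome,
)


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic dataset at the default study conditions."""
    cfg = SimulationConfig(seed=7)
    genome, annotation, truth = simulate_genome(cfg)
    replicates = simulate_chip_replicates(truth, cfg, genome)
    counts = simulate_counts(truth, cfg, annotation)
    return {
        "config": cfg,
        "genome": genome,
        "annotation": annotation,
        "truth": truth,
        "replicates": replicates,
        "counts": counts,
    }


@pytest.fixture(scope="session")
def table1():
    from quartet_hub.classify import load_direct_target_table

    return load_direct_target_table()
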