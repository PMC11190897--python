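import numpy as np
import pandas as pd
import pytest

from nocimap import simulate
from nocimap.bulk_de import CountMatrix


@pytest.fixture(scope="session")
def toy_counts() -> CountMatrix:
    """5-gene, 2x2-sample matrix small enough to check by hand."""
    counts = pd.DataFrame(
        {
            "s1": [0, 100, 5000, 1, 200],
            "s2": [0, 120, 4000, 0, 180],
            "s3": [0, 0, 6000, 2, 250],
            "s4": [0, 1, 5500, 0, 210],
        },
        index=[f"g{i}" for i in range(5)],
    )
    groups = pd.Series(["A", "A", "B", "B"], index=counts.columns)
    return CountMatrix(counts, groups)


@pytest.fixture(scope="session")
def nb_sim_null():
    """Null NB simulation: no DE, phi=0.2, 5 vs 5, 2000 genes."""
    cfg = simulate.SimulationConfig(
        seed=11, n_genes=2000, n_samples_per_group=5, n_de_genes=0, dispersion=0.2
    )
    return simulate.simulate_bulk_counts(cfg)


@pytest.fixture(scope="session")
def nb_sim_planted():
    """Planted DE at 8 vs 8, phi=0.2."""
    cfg = simulate.SimulationConfig(
        seed=5, n_genes=2000, n_samples_per_group=8, n_de_genes=100, dispersion=0.2
    )
    return simulate.simulate_bulk_counts(cfg)


@pytest.fixture(scope="session")
def neuron_matrix():
    """Single-neuron TPM matrix with planted receptor/marker coexpression."""
    specs = [
        simulate.GeneSpec("Agtr1a", default_rate=0.55),
        simulate.GeneSpec("Agtr1b", default_rate=0.25),
        simulate.GeneSpec("Il1r1", default_rate=0.8),
        simulate.GeneSpec("Scn10a", conditional_on=("Agtr1a", 0.95, 0.6)),
        simulate.GeneSpec("Trpv1", conditional_on=("Agtr1a", 0.8, 0.5)),
    ]
    return simulate.simulate_neuron_expression(314, {"colonic": 1.0}, specs, seed=3)
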