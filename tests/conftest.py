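import numpy as np
import pandas as pd
import pytest

from selnet import GenotypePanel, PopulationSpec, simulate_panel


@pytest.fixture(scope="session")
def two_pop_panel() -> GenotypePanel:
    """Moderately differentiated two-population panel shared across tests."""
    pops = [PopulationSpec("A", "West", 30, 0.05), PopulationSpec("B", "East", 30, 0.05)]
    return simulate_panel(pops, 5_000, seed=11)


@pytest.fixture()
def tiny_panel() -> GenotypePanel:
    """Hand-built four-sample, three-SNP panel with known genotypes."""
    genotypes = np.array(
        [
            [0, 1, 2],
            [1, 1, -1],
            [2, 1, 0],
            [2, 1, 0],
        ],
        dtype=np.int8,
    )
    samples = pd.DataFrame(
        {
            "sample_id": ["a1", "a2", "b1", "b2"],
            "population": ["A", "A", "B", "B"],
            "continent": ["West", "West", "East", "East"],
        }
    )
    return GenotypePanel(
        genotypes=genotypes,
        chrom=np.array(["1", "1", "2"], dtype=object),
        pos=np.array([100, 200, 100]),
        ids=np.array(["s1", "s2", "s3"], dtype=object),
        samples=samples,
        chrom_lengths={"1": 1000, "2": 1000},
    )
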