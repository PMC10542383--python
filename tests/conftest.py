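import numpy as np
import pytest

import refbias as rb


@pytest.fixture
def toy_gm():
    """Four samples, two populations, four hand-readable sites."""
    return rb.GenotypeMatrix(
        sample_ids=["a1", "a2", "b1", "b2"],
        chrom=np.array(["chr1"] * 4, dtype=object),
        pos=np.array([10, 20, 30, 40]),
        ref=np.array(["A"] * 4, dtype=object),
        alt=np.array(["G"] * 4, dtype=object),
        genotypes=np.array(
            [
                [2, 1, 0, 2],
                [2, 0, 0, -1],
                [0, 1, 1, 0],
                [0, 2, 2, 0],
            ],
            dtype=np.int8,
        ),
    )


@pytest.fixture
def toy_popmap():
    return rb.PopulationMap(
        population={"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        super_population={"a1": "X", "a2": "X", "b1": "Y", "b2": "Y"},
    )


@pytest.fixture(scope="session")
def null_quartet():
    """Shared gamma=0 simulation used by several statistical checks."""
    cfg = rb.SimulationConfig(seed=1, chrom_length=400_000, gamma=0.0)
    gm, popmap, truth = rb.simulate_quartet_genotypes(cfg)
    return cfg, gm, popmap, truth


@pytest.fixture(scope="session")
def tract_quartet():
    """Shared gamma=1 simulation with two planted 60-kb tracts."""
    cfg = rb.SimulationConfig(
        seed=2,
        chrom_length=500_000,
        gamma=1.0,
        tracts=((100_000, 160_000), (300_000, 360_000)),
    )
    gm, popmap, truth = rb.simulate_quartet_genotypes(cfg)
    return cfg, gm, popmap, truth
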