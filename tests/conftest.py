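import numpy as np
import pandas as pd
import pytest

from fragsig.synthetic_data import SimulationConfig, make_genome


def tiny_config(**overrides) -> SimulationConfig:
    """A small, fast simulation setup for unit tests."""
    defaults = dict(
        genome_length=600_000,
        n_regions=8,
        edge_clearance=26_000,
        depth=6.0,
        dip_sigmas=(150.0, 800.0, 3_500.0),
        dip_amplitudes=(0.25, 0.3, 0.15),
        n_lowmap_patches=6,
        seed=1234,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_genome():
    return make_genome(tiny_config())


@pytest.fixture
def fragment_table():
    return pd.DataFrame(
        {
            "chrom": ["chr1"] * 6,
            "start": [100, 200, 300, 1000, 2000, 3000],
            "end": [267, 350, 467, 1120, 2200, 3310],
            "mapq": [60, 60, 19, 60, 60, 60],
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
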