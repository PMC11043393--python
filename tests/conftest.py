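import numpy as np
import pandas as pd
import pytest

from rtturnover import simulate
from rtturnover.core import ElementSet
from rtturnover.timing import ReplicationTrack


@pytest.fixture
def small_config():
    """A compact synthetic genome: 50 x 200 kb bins, 4 cell types."""
    return simulate.SimulationConfig(genome_size=10_000_000, seed=7)


@pytest.fixture
def bundle(small_config):
    return simulate.simulate_all(small_config)


@pytest.fixture
def simple_track():
    n = 20
    starts = np.arange(n) * 200_000
    vals = np.linspace(-2, 2, n)
    return ReplicationTrack(
        "ct1",
        pd.DataFrame(
            {"chrom": "chr1", "start": starts, "end": starts + 200_000, "value": vals}
        ),
    )


def make_elements(rows, **extra):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    for key, vals in extra.items():
        df[key] = vals
    return ElementSet(df)


@pytest.fixture
def elements_factory():
    return make_elements
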