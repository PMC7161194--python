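import numpy as np
import pandas as pd
import pytest

from aimpanel.popdata import GenotypeMatrix, FrequencyTable
from aimpanel.simulate import SimulationConfig, simulate_cohort


def marker_frame(n, chrom="1", spacing=1000):
    """Simple marker metadata frame for hand-built fixtures."""
    return pd.DataFrame(
        {
            "marker_id": [f"m{i}" for i in range(n)],
            "chrom": chrom,
            "pos": np.arange(1, n + 1) * spacing,
            "ref": "A",
            "alt": "G",
        }
    )


@pytest.fixture
def tiny_genotypes():
    """4 samples x 3 markers with one missing call."""
    dos = np.array(
        [
            [0, 1, 2],
            [1, 2, 0],
            [2, np.nan, 1],
            [1, 0, 0],
        ],
        dtype=float,
    )
    return GenotypeMatrix(dos, marker_frame(3), ["s1", "s2", "s3", "s4"])


@pytest.fixture
def two_pop_freqs():
    """2 populations x 4 markers with a fixed difference at m0."""
    mk = marker_frame(4)
    freqs = np.array(
        [
            [1.0, 0.3, 0.2, 0.5],
            [0.0, 0.3, 0.8, 0.5],
        ]
    )
    return FrequencyTable(freqs, mk, ["popA", "popB"])


@pytest.fixture(scope="session")
def small_cohort():
    """Simulated 4-way cohort reused across read-only tests."""
    cfg = SimulationConfig(
        n_markers=2000, n_admixed=150, n_reference_per_pop=25, seed=11
    )
    return simulate_cohort(cfg)
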