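import numpy as np
import pandas as pd
import pytest

from lipidsig.datatypes import IntensityTable
from lipidsig.simulate import SimulationConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_table():
    """Hand-sized intensity table: 4 study samples + 3 QC rows, 3 features."""
    samples = ["a", "b", "c", "d", "q1", "q2", "q3"]
    intens = pd.DataFrame(
        {
            "f1": [100.0, 200, 400, 800, 100, 100, 100],
            "f2": [10.0, 20, 30, 40, 50, 100, 150],
            "f3": [5.0, 5, 5, 5, 10, 10, 10],
        },
        index=samples,
    )
    modes = pd.Series({"f1": "pos", "f2": "pos", "f3": "neg"})
    internal = pd.DataFrame(
        {"pos": [100.0] * 7, "neg": [10.0] * 7}, index=samples
    )
    qc = pd.Series([False] * 4 + [True] * 3, index=samples)
    return IntensityTable(intens, modes, internal, qc)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort shared across tests (one generation)."""
    cfg = SimulationConfig(n_gc=80, n_hd=80, n_features=120,
                           n_informative=16,
                           block_sizes=[4] * 4 + [8] * 5,
                           n_prognostic=12, n_unstable_qc=8, seed=7)
    return generate_cohort(cfg)
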