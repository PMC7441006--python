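import numpy as np
import pandas as pd
import pytest

from sigstrat.cohort_io import ExpressionMatrix, Scale
from sigstrat.synthetic_data import (
    LCM_LIKE,
    TCGA_LIKE,
    ChipSimConfig,
    simulate_chip,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def tcga_cohort():
    """Large unpaired cohort (n=499) with planted latent activity."""
    return simulate_cohort(TCGA_LIKE)


@pytest.fixture(scope="session")
def lcm_cohort():
    """Small paired cohort (n=19, 8 high / 11 low foci)."""
    return simulate_cohort(LCM_LIKE)


@pytest.fixture(scope="session")
def chip_sim():
    """Control + three knockdown coverage tracks, planted gamma/phi."""
    return simulate_chip(ChipSimConfig(seed=11))


@pytest.fixture()
def tiny_matrix():
    values = pd.DataFrame(
        {"s1": [5.0, 4.0, 3.0, 2.0, 1.0], "s2": [1.0, 2.0, 3.0, 4.0, 5.0]},
        index=["G1", "G2", "G3", "G4", "G5"],
    )
    return ExpressionMatrix(values=values, scale=Scale.log2CPM)
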