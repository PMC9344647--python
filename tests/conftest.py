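import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from endomap import simulate_cohort
from endomap.simulate import null_config, power_config


@pytest.fixture(scope="session")
def power_cohort():
    """Reference mediation cohort: 2 planted SNPs, 30 causal ROIs, n=600."""
    return simulate_cohort(power_config(seed=20_001))


@pytest.fixture(scope="session")
def null_cohort():
    """All-null cohort: no genetic, diagnostic or covariate effects."""
    return simulate_cohort(null_config(seed=20_002))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
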