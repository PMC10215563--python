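import logging

import numpy as np
import pandas as pd
import pytest

from vrintercept.config import SessionConfig

logging.getLogger("vrintercept").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def cfg() -> SessionConfig:
    return SessionConfig()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def probe_design() -> pd.DataFrame:
    """43 participants x 4 blocks x 6 probes, balanced 2x2 conditions."""
    rows = [
        {"participant": p, "pressure": pr, "feedback": fe}
        for p in range(43)
        for (pr, fe) in [(0, 0), (0, 1), (1, 0), (1, 1)]
        for _ in range(6)
    ]
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def hit_trial(cfg):
    """One clean (jitter/dropout-free) intercepted trial."""
    from vrintercept.synthdata import simulate_trial
    return simulate_trial(cfg, "normal", True, np.random.default_rng(7))


@pytest.fixture(scope="session")
def miss_trial(cfg):
    from vrintercept.synthdata import simulate_trial
    return simulate_trial(cfg, "elastic", False, np.random.default_rng(8))
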