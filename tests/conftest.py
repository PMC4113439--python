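import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from tessella import ChannelStats, CohortConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20140728)


def make_stats(r: float, g: float, b: float, count: int = 100) -> ChannelStats:
    """ChannelStats with the given channel means (other fields consistent)."""
    return ChannelStats(
        mean=(r, g, b),
        sd=(0.0, 0.0, 0.0),
        minimum=(r, g, b),
        maximum=(r, g, b),
        median=(r, g, b),
        count=count,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-eye synthetic cohort shared by the slower integration tests."""
    return generate_cohort(CohortConfig(n=12, seed=99))
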