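import numpy as np
import pytest

import minifil as mf

#: directory with optional real heavy-chain sequences (see
#: scripts/fetch_sequences.py); sequence-scale tests skip when absent.
from pathlib import Path

ISOFORM_DIR = Path(__file__).resolve().parents[1] / "data" / "isoforms"


@pytest.fixture(scope="session")
def default_rod():
    """The default synthetic 196-site-repeat rod (1085 sites, ~158 nm)."""
    return mf.make_periodic_rod()


@pytest.fixture(scope="session")
def e_params():
    return mf.ElectrostaticParams()


@pytest.fixture(scope="session")
def wlc_params():
    return mf.WLCParams()


@pytest.fixture(scope="session")
def toy_pair():
    """Two short random chains for oracle comparisons."""
    rng = np.random.default_rng(7)
    qa = rng.choice([-2.0, 0.0, 2.0], 60, p=[0.25, 0.5, 0.25])
    qb = rng.choice([-2.0, 0.0, 2.0], 50, p=[0.25, 0.5, 0.25])
    return mf.ChargeChain("toyA", qa), mf.ChargeChain("toyB", qb)


@pytest.fixture(scope="session")
def synthetic_profiles(default_rod, e_params, wlc_params):
    """Contact-time profiles of the default rod, both orientations (cached)."""
    return {
        orient: mf.contact_time_profile(
            default_rod, default_rod, orient, e_params=e_params, wlc_params=wlc_params
        )
        for orient in ("parallel", "antiparallel")
    }


@pytest.fixture(scope="session")
def synthetic_scan(default_rod, e_params):
    """Parallel straight-rod self-scan of the default rod (cached)."""
    return mf.stagger_scan_straight(
        default_rod, default_rod, "parallel", params=e_params
    )
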