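import numpy as np
import pytest

from mtarch.lattice import LatticeSpec
from mtarch.synth import build_lattice, decorate, render


@pytest.fixture(scope="session")
def decorated_b_volume():
    """13_3 B-lattice volume, skew -0.4 deg, kinesin-decorated, noiseless."""
    lat = decorate(build_lattice(LatticeSpec(skew_deg=-0.4), 70.0))
    return render(lat, mode="volume")


@pytest.fixture(scope="session")
def projection_skew1():
    """Undecorated 13-PF projection at +1 deg skew (moire 295 nm)."""
    return render(build_lattice(LatticeSpec(skew_deg=1.0), 800.0))


@pytest.fixture(scope="session")
def straight_projection():
    """Undecorated unskewed 13_3 projection (no moire within the box)."""
    return render(build_lattice(LatticeSpec(), 400.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
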