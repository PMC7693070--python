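import numpy as np
import pytest

import zshim


@pytest.fixture(scope="session")
def phantom_seq():
    return zshim.phantom_params()


@pytest.fixture(scope="session")
def invivo_seq():
    return zshim.invivo_params()


@pytest.fixture(scope="session")
def pulse():
    return zshim.sinc_hanning_pulse()


@pytest.fixture(scope="session")
def gslice_phantom(phantom_seq):
    return zshim.slice_select_gradient(phantom_seq)


@pytest.fixture(scope="session")
def profile60(pulse, gslice_phantom, phantom_seq):
    """Bloch profile for the 60-degree phantom protocol (ξ=1, full relaxation)."""
    return zshim.simulate_profile(
        pulse, 60.0, 1.0, gslice_phantom,
        slice_thickness=phantom_seq.slice_thickness,
    )


@pytest.fixture(scope="session")
def rect_profile():
    return zshim.rectangular_profile(4e-3)


@pytest.fixture(scope="session")
def agar_phantom():
    return zshim.make_phantom("uniform-agar", seed=1)


def small_params(n_echoes=8, n_unshimmed=2):
    """Tiny synthetic protocol for fast unit tests."""
    te = 3e-3 + 4e-3 * np.arange(n_echoes)
    return zshim.SequenceParams(
        echo_times=te,
        n_unshimmed_echoes=n_unshimmed,
        delta_te_shimmed=4e-3,
        tr=2.0,
        te_navigator=float(te[-1] + 4e-3),
    )
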