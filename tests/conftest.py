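import numpy as np
import pytest

from cordivim import BValueScheme, IVIMParams, forward_signal

#: Cohort mean parameters (voxel-wise one-step, session 1) used as ground truth.
WM_TRUTH = dict(S0=1.0, F=0.0545, Dstar=24.41e-3, D=3.74e-4)
GM_TRUTH = dict(S0=1.0, F=0.0961, Dstar=17.14e-3, D=4.17e-4)


@pytest.fixture(scope="session")
def scheme() -> BValueScheme:
    return BValueScheme()


@pytest.fixture(scope="session")
def wm_params() -> IVIMParams:
    return IVIMParams(**WM_TRUTH)


@pytest.fixture(scope="session")
def gm_params() -> IVIMParams:
    return IVIMParams(**GM_TRUTH)


@pytest.fixture(scope="session")
def wm_decay(wm_params, scheme):
    return forward_signal(wm_params, scheme)


@pytest.fixture(scope="session")
def gm_decay(gm_params, scheme):
    return forward_signal(gm_params, scheme)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
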