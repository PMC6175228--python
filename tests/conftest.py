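import numpy as np
import pytest
from hypothesis import settings

from fastwhiten.design import assemble_design

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def intercept_design():
    def make(n, tr=1.0):
        return assemble_design(None, n, tr)

    return make


def random_spd(rng, n, cond_scale=1.0):
    """Random well-conditioned SPD matrix of size n."""
    A = rng.standard_normal((n, n))
    Q, _ = np.linalg.qr(A)
    eigs = rng.uniform(0.5, 2.0 * cond_scale, n)
    return (Q * eigs) @ Q.T
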