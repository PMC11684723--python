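import numpy as np
import pytest

from mppvae.linear_gaussian import make_linear_gaussian_jmi


@pytest.fixture(autouse=True)
def _silence_symmetrize_warning():
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def lg_jmi():
    """Tractable linear-Gaussian joint-mark-intensity instance with exact
    posterior encoders (closed-form evidences available)."""
    return make_linear_gaussian_jmi(d_x=2, d_k=3, d_z=1, lambda0=2.0, seed=7)


@pytest.fixture
def lg_point(lg_jmi, rng):
    """A fixed evaluation point (x, k) for the tractable instance."""
    x = rng.standard_normal(2)
    k = rng.standard_normal(3)
    return x, k


def random_block_tridiag(rng, R, d, coupling=0.3, diag_boost=None):
    """Random SPD block-tridiagonal instance (shared test helper)."""
    from mppvae.block_tridiag import BlockTridiagonalSPD
    diag = np.empty((R, d, d))
    for r in range(R):
        B = rng.standard_normal((d, d))
        diag[r] = B @ B.T + (diag_boost or (d + 2.0)) * np.eye(d)
    off = coupling * rng.standard_normal((max(R - 1, 0), d, d))
    return BlockTridiagonalSPD(diag, off)
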