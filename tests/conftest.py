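import numpy as np
import pytest

from lffusion import optics as O
from lffusion import phantom as P


@pytest.fixture(scope="session")
def desk_lfm():
    cfg, mla = O.lfm_desk_config()
    psf = O.compute_lfm_psf(cfg, mla, n_offsets=12)
    return cfg, mla, psf


@pytest.fixture(scope="session")
def desk_flfm():
    cfg, mla = O.flfm_desk_config()
    psf = O.compute_flfm_psf(cfg, mla, view_spacing_px=36.0)
    return cfg, mla, psf


@pytest.fixture(scope="session")
def desk_sample(desk_lfm, desk_flfm):
    _, _, lpsf = desk_lfm
    _, _, fpsf = desk_flfm
    cfg = P.tubulin_desk_preset()
    return P.make_sample(cfg, lpsf, fpsf, sample_id="fixture", seed=123)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
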