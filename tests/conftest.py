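import pytest

from retenphys.pirt import PirtFit, RatePair, fit_pirt
from retenphys.retentostat import RetentostatConfig

# Reference physiology used throughout the tests: a complex-I-positive
# wild-type-like strain and a complex-I-deficient strain with weaker
# respiratory energy coupling.
WT_MS, WT_YMAX = 0.0142, 0.545
CXI_MS, CXI_YMAX = 0.0241, 0.485


def pirt_line_pairs(m_s: float, y_max: float, mus) -> list[RatePair]:
    """Exactly collinear rate pairs on q_S = mu/y_max + m_S."""
    return [RatePair(mu_h=mu, q_s_g_g_h=mu / y_max + m_s) for mu in mus]


@pytest.fixture(scope="session")
def wt_fit() -> PirtFit:
    return fit_pirt(pirt_line_pairs(WT_MS, WT_YMAX, [0.025, 0.1]))


@pytest.fixture(scope="session")
def cxi_fit() -> PirtFit:
    return fit_pirt(pirt_line_pairs(CXI_MS, CXI_YMAX, [0.025, 0.1]))


@pytest.fixture()
def config() -> RetentostatConfig:
    return RetentostatConfig()
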