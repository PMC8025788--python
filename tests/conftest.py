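import numpy as np
import pytest

from recakin import DomainKinetics, RateParams, WLCParams, propagate_exact
from recakin.wlc import CoverageCurve


@pytest.fixture(scope="session")
def wlc_params():
    return WLCParams()


@pytest.fixture(scope="session")
def paper_rates():
    """Reference best-fit rates of the assay conditions emulated throughout."""
    return RateParams(kn=1.05e-3, kg_fast=5.27e-4, r=0.10, n_sites=10700)


@pytest.fixture(scope="session")
def two_domain_truth():
    """Two-domain ground truth whose alternative decomposition scenario
    (second-domain fast front reaching the molecule end) requires a
    negative velocity: v2_slow < v1_slow."""
    d1 = DomainKinetics(t_nuc=500.0, x_nuc=0.2, v_fast=8e-4, v_slow=1.0e-4, fast_side="left")
    d2 = DomainKinetics(t_nuc=1200.0, x_nuc=0.7, v_fast=8e-4, v_slow=0.7e-4, fast_side="left")
    return [d1, d2]


@pytest.fixture(scope="session")
def two_domain_curve(two_domain_truth):
    """Noiseless L(t) of the two-domain scenario, 1 Hz sampling, with a
    measured tail beyond saturation."""
    L0 = 12.0
    pw = propagate_exact(two_domain_truth)
    t = np.arange(0.0, pw.knot_t[-1] + 1500.0, 1.0)
    curve = CoverageCurve.from_length(t, L0 * (1.0 + pw.phi_at(t) / 2.0), L0)
    return curve, pw
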