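import warnings

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from pebri.bv import BVEstimates
from pebri.model import PEBParameters

# biological-variation parameter sets used across the suite: an albumin-like
# analyte (tight within-subject control), a phosphate-like one (moderate CVs)
# and an 11-deoxycortisol-like one (within-subject variation dominating)
BV_ROWS = {
    "albumin": dict(mu_pop_original=4.522, cv_g_pct=6.0, cv_i_pct=2.3, cv_a_pct=1.8),
    "phosphate": dict(mu_pop_original=3.327, cv_g_pct=13.6, cv_i_pct=9.5, cv_a_pct=1.7),
    "11doc": dict(mu_pop_original=31.91, cv_g_pct=33.5, cv_i_pct=50.0, cv_a_pct=5.3),
}


@pytest.fixture(scope="session")
def albumin_boxcox_params() -> PEBParameters:
    """Albumin-like parameters on a Box-Cox working scale."""
    return PEBParameters(mu_pop=3.181, sigma_pop=0.241, b1=0.66, scale="boxcox", lambda_=0.890)


@pytest.fixture(scope="session")
def albumin_bv() -> BVEstimates:
    return BVEstimates(**BV_ROWS["albumin"])


@pytest.fixture(scope="session")
def phosphate_bv() -> BVEstimates:
    return BVEstimates(**BV_ROWS["phosphate"])


@pytest.fixture(scope="session")
def doc11_bv() -> BVEstimates:
    return BVEstimates(**BV_ROWS["11doc"])


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Silence advisory small-sample warnings that tests trigger on purpose."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="only .* (first results|pairs|calibration pairs)")
        yield
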