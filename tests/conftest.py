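"""Shared fixtures.

The expensive coupled simulations (19-year disease phase + 2-year
treatment) are session-scoped and shared between the behavioural unit tests
and the acceptance tests; the disease pre-phase itself is shared across
regimens and variants through ``pre_cache``.
"""

import numpy as np
import pytest

from bonepkpd.bcpm import BCPMParams
from bonepkpd.coupling import PDParams, simulate_treatment
from bonepkpd.pk import PKParams
from bonepkpd.reference import PKPD_VARIANT_FITS


@pytest.fixture(scope="session")
def bcpm_default():
    return BCPMParams.default()


@pytest.fixture(scope="session")
def pkpd1_pk():
    return PKParams(**PKPD_VARIANT_FITS["pkpd1"]["pk"], k_el_BC=0.0)


@pytest.fixture(scope="session")
def pkpd1_pd():
    v = PKPD_VARIANT_FITS["pkpd1"]
    return PDParams(pi_act=v["pi_act"], pi_rep=v["pi_rep"], f_sat=v["f_sat"])


@pytest.fixture(scope="session")
def pre_cache():
    """Shared cache of the drug-free 19-year disease phase per site."""
    return {}


@pytest.fixture(scope="session")
def treat15_weekly(bcpm_default, pkpd1_pk, pkpd1_pd, pre_cache):
    return simulate_treatment(15.0, "weekly70", "pkpd1", pkpd1_pk,
                              bcpm_default, pkpd1_pd, pre_cache=pre_cache)


@pytest.fixture(scope="session")
def treat25_weekly(bcpm_default, pkpd1_pk, pkpd1_pd, pre_cache):
    return simulate_treatment(25.0, "weekly70", "pkpd1", pkpd1_pk,
                              bcpm_default, pkpd1_pd, pre_cache=pre_cache)


@pytest.fixture(scope="session")
def treat15_daily(bcpm_default, pkpd1_pk, pkpd1_pd, pre_cache):
    return simulate_treatment(15.0, "daily10", "pkpd1", pkpd1_pk,
                              bcpm_default, pkpd1_pd, pre_cache=pre_cache)


def post_treatment(ts):
    """(t_since_treatment_start, slice) for the treatment phase samples."""
    i0 = int(np.searchsorted(ts.t, ts.treatment_start))
    return ts.t[i0:] - ts.treatment_start, i0
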