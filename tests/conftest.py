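import numpy as np
import pytest

from mimelog import DEFAULT_CONSTANTS, PituitaryParams, ThyroidParams


@pytest.fixture(scope="session")
def constants():
    return DEFAULT_CONSTANTS


@pytest.fixture
def rng():
    return np.random.default_rng(20171120)


def bisect_set_point(s, phi, k_t, d_t, iters=200):
    """Independent bisection oracle for the nullcline intersection.

    Pure bisection on g(FT4) = FT4 − K_T·TSH/(D_T+TSH) with
    TSH = S·exp(−phi·FT4), over [0, K_T]; no shared code with the solver.
    """
    lo, hi = 0.0, k_t
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        tsh = s * np.exp(-phi * mid)
        if mid - k_t * tsh / (d_t + tsh) <= 0.0:
            lo = mid
        else:
            hi = mid
    ft4 = 0.5 * (lo + hi)
    return ft4, s * np.exp(-phi * ft4)


@pytest.fixture(scope="session")
def bisection_oracle():
    return bisect_set_point
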