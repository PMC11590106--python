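"""Shared fixtures: paper-grade binding constants and an independent
bisection oracle for the competitive-binding mass balance."""

from __future__ import annotations

import numpy as np
import pytest

from glucompete import BindingConstants, mgdl_to_molar

# binding constants of the three labeled mannose ligands vs PEG-ConA,
# as reciprocals of the measured association constants
K_TETRAOSE = 5.4e-8
K_TRIOSE = 1.0 / 5.33e6
K_BIOSE = 1.0 / 1.73e6
K_GLUCOSE = 2.5e-3

G400_MOLAR = mgdl_to_molar(400.0)


def bisect_c_free(K_M, K_G, M0, C0, G0, iters=200):
    """Bisection on the monotone combined mass balance
    f(C) = C + C*M0/(K_M+C) + C*G0/(K_G+C) - C0, root in [0, C0].

    Independent of the cubic solver: plain interval halving.
    """

    def f(C):
        return C + C * M0 / (K_M + C) + C * G0 / (K_G + C) - C0

    lo, hi = 0.0, C0
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if f(mid) <= 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def bisect_free_fraction(K_M, K_G, M0, C0, G0):
    C = bisect_c_free(K_M, K_G, M0, C0, G0)
    return K_M / (K_M + C)


@pytest.fixture
def tetraose_constants():
    return BindingConstants(K_M=K_TETRAOSE, K_G=K_GLUCOSE)


@pytest.fixture
def triose_constants():
    return BindingConstants(K_M=K_TRIOSE, K_G=K_GLUCOSE)


@pytest.fixture
def biose_constants():
    return BindingConstants(K_M=K_BIOSE, K_G=K_GLUCOSE)


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
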