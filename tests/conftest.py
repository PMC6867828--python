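"""Shared fixtures and independent numerical oracles for the test suite."""

import numpy as np
import pytest
from scipy.optimize import brentq

from actinpace import AffinityConstant, CompetitionMixture


def competition_oracle(mix: CompetitionMixture) -> dict:
    """Independent equilibrium solve: bisection on free actin.

    Solves conservation + mass action by bracketed root-finding on the
    free receptor concentration only; shares no code with the package's
    closed-form path.
    """
    a0, p0, w0 = mix.a_total, mix.p_total, mix.w_total
    kp, kw = mix.kp.kd, mix.kw.kd

    def excess(a):
        return a * (1.0 + p0 / (kp + a) + w0 / (kw + a)) - a0

    if a0 == 0.0:
        a_free = 0.0
    else:
        a_free = brentq(excess, 0.0, a0, xtol=5e-324, rtol=8.9e-16, maxiter=200)
    pa = p0 * a_free / (kp + a_free)
    wa = w0 * a_free / (kw + a_free)
    return {
        "a_free": a_free,
        "p_free": p0 - pa,
        "w_free": w0 - wa,
        "pa": pa,
        "wa": wa,
    }


def random_mixtures(n, seed):
    """Random competition mixtures: totals 1 nM-1 mM, Kds 1 nM-100 uM."""
    rng = np.random.default_rng(seed)
    lo_t, hi_t = np.log10(1e-9), np.log10(1e-3)
    lo_k, hi_k = np.log10(1e-9), np.log10(1e-4)
    for _ in range(n):
        a0, p0, w0 = 10.0 ** rng.uniform(lo_t, hi_t, 3)
        kp, kw = 10.0 ** rng.uniform(lo_k, hi_k, 2)
        yield CompetitionMixture(a0, p0, w0, AffinityConstant(kp), AffinityConstant(kw))


@pytest.fixture
def wt_mix():
    """Anisotropy-assay template: 150 nM actin, 4 nM probe."""
    return CompetitionMixture(
        a_total=150e-9, p_total=0.0, w_total=4e-9,
        kp=AffinityConstant(18e-9), kw=AffinityConstant(100e-9),
    )
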