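"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math
from math import comb

import numpy as np
import pytest

from vulnscreen import synthetic_data


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_library():
    return synthetic_data.gen_library(50, 2, rng_seed=7)


def rsa_bruteforce_log10p(ranks: list[int], n_total: int) -> float:
    """Brute-force RSA p-value by direct hypergeometric tail enumeration.

    For ascending ranks r_1 < ... < r_n of one gene's siRNAs among
    ``n_total`` scored siRNAs: min over i of P(X >= i) with
    X ~ Hypergeom(population n_total, successes n, draws r_i), computed by
    exact summation with integer binomial coefficients.
    """
    ranks = sorted(ranks)
    n = len(ranks)
    best = 1.0
    for i, r in enumerate(ranks, start=1):
        denom = comb(n_total, r)
        tail = sum(
            comb(n, k) * comb(n_total - n, r - k)
            for k in range(i, min(n, r) + 1)
        )
        best = min(best, tail / denom)
    return math.log10(best) if best > 0 else -math.inf


@pytest.fixture
def rsa_oracle():
    return rsa_bruteforce_log10p
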