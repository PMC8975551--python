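"""Shared builders for the test suite.

All stochastic tests are seeded; statistical tolerances are 3-4 standard
errors of the quantity under test so reruns are deterministic and stable.
"""

from __future__ import annotations

import numpy as np
import pytest

from bicoidms2 import (
    BcdGradient,
    KineticRates,
    PromoterArchitecture,
    PromoterModel,
    SignalKernel,
)


def make_model(n_sites: int = 3, k_threshold: int = 2, *, kb: float = 0.05,
               ku: float = 0.02, k_on_base: float = 0.05,
               k_off_promoter: float = 0.1, rnap_rate: float = 0.1,
               scaling: str = "binomial") -> PromoterModel:
    """Small promoter model with aggregate unbinding k_-i = i * ku."""
    rates = KineticRates(
        kb=kb,
        k_off_site=tuple(i * ku for i in range(1, n_sites + 1)),
        k_on_base=k_on_base,
        k_off_promoter=k_off_promoter,
        rnap_rate=rnap_rate,
    )
    arch = PromoterArchitecture(n_sites=n_sites, k_threshold=k_threshold,
                                activation_scaling=scaling)
    return PromoterModel(arch, rates)


def random_small_model(rng: np.random.Generator) -> tuple[PromoterModel, float]:
    """Random model with N <= 4 plus a concentration, for SSA/ME checks."""
    n = int(rng.integers(2, 5))
    k = int(rng.integers(1, n + 1))
    model = make_model(
        n, k,
        kb=float(rng.uniform(0.02, 0.2)),
        ku=float(rng.uniform(0.005, 0.05)),
        k_on_base=float(rng.uniform(0.01, 0.1)),
        k_off_promoter=float(rng.uniform(0.02, 0.2)),
        rnap_rate=float(rng.uniform(0.02, 0.2)),
    )
    return model, float(rng.uniform(0.2, 1.5))


@pytest.fixture
def small_model() -> PromoterModel:
    return make_model()


@pytest.fixture
def gradient() -> BcdGradient:
    return BcdGradient(c0=1.0, lambda_decay=15.0)


@pytest.fixture
def kernel() -> SignalKernel:
    return SignalKernel()
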