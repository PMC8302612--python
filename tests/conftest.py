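import numpy as np
import pytest

from burstkin import (
    PromoterModel,
    SignalKernel,
    build_model,
    forward_distribution,
)


@pytest.fixture(scope="session")
def sna_model() -> PromoterModel:
    """Fast two-state promoter: T_OFF = 24 s, T_ON = 242 s, one
    initiation every 9 s while ON."""
    return build_model(k1_plus=1.0 / 24.0, k1_minus=1.0 / 242.0, k_ini=1.0 / 9.0)


@pytest.fixture(scope="session")
def sna_params(sna_model):
    return forward_distribution(sna_model)


@pytest.fixture(scope="session")
def pause_model() -> PromoterModel:
    """Three-state promoter with a long-lived non-obligatory pause,
    timescales separated by more than 4x."""
    return build_model(
        k1_plus=1.0 / 15.0,
        k1_minus=1.0 / 50.0,
        k_ini=1.0 / 6.0,
        k2_plus=1.0 / 300.0,
        k2_minus=1.0 / 40.0,
    )


@pytest.fixture(scope="session")
def pause_params(pause_model):
    return forward_distribution(pause_model)


@pytest.fixture(scope="session")
def kernel() -> SignalKernel:
    return SignalKernel()
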