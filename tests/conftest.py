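import numpy as np
import pytest

from direpi import CrossMeans, PowerFit, QuadFit


@pytest.fixture
def chicken_cross_means() -> CrossMeans:
    """Published 8-week body-weight means of the two divergently selected
    parental populations and their F1/F2 intercrosses (grams)."""
    return CrossMeans(P1=170.0, P2=1412.0, F1=650.0, F2=624.0)


@pytest.fixture
def power_fit_printed() -> PowerFit:
    """Power-model estimates reported for the four-QTL body-weight data."""
    return PowerFit(mu=0.0, alpha=13.0, beta=2.18)


@pytest.fixture
def quad_fit_printed() -> QuadFit:
    """Quadratic-model estimates reported for the same data."""
    return QuadFit(mu=0.0, alpha=23.1, beta_prime=8.3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
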