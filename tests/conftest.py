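import numpy as np
import pytest

from capritrack.hmm import GMMEmission, HMMModel, TransitionMatrix


def make_random_model(rng: np.random.Generator, m: int = 2) -> HMMModel:
    """Random valid 3-state model with m-component diagonal mixtures."""
    T = rng.dirichlet(np.ones(3), size=3)
    pi = rng.dirichlet(np.ones(3))
    emissions = tuple(
        GMMEmission(
            state=s,
            m=m,
            weights=rng.dirichlet(np.ones(m)),
            means=rng.normal(0.0, 2.0, (m, 3)),
            variances=rng.uniform(0.1, 1.0, (m, 3)),
            loglik=0.0,
            aic=0.0,
        )
        for s in range(3)
    )
    return HMMModel(TransitionMatrix(T=T, pi=pi), emissions)


def make_separated_model(gap: float = 20.0) -> HMMModel:
    """Single-Gaussian emissions with state means `gap` sds apart."""
    T = np.full((3, 3), 0.1) + np.eye(3) * 0.7
    pi = np.full(3, 1.0 / 3.0)
    emissions = tuple(
        GMMEmission(
            state=s,
            m=1,
            weights=np.array([1.0]),
            means=np.array([[s * gap, s * gap, s * gap]]),
            variances=np.ones((1, 3)),
            loglik=0.0,
            aic=0.0,
        )
        for s in range(3)
    )
    return HMMModel(TransitionMatrix(T=T, pi=pi), emissions)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
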