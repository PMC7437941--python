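import numpy as np
import pytest

from hbfm import ExpressionCounts, ModelState


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_state(G=5, N=8, F=3, seed=3, alpha=None):
    """Random valid ModelState (and matching shapes) for update tests."""
    r = np.random.default_rng(seed)
    if alpha is None:
        alpha = r.choice([-1, 0, 1], size=(G, F), p=[0.25, 0.5, 0.25])
    else:
        alpha = np.asarray(alpha)
        G, F = alpha.shape
    phi = r.uniform(0.3, 0.9, F)
    return ModelState(
        beta=r.gamma(3.0, 2.0, G),
        alpha=alpha.astype(np.int8),
        lam=np.exp(r.normal(0.0, np.sqrt(phi)[None, :], (N, F))),
        phi=phi,
        theta=r.uniform(0.2, 0.8, F),
        h1=0.2,
        h2=0.8,
    )


def counts_from_state(state, seed=9, scale=1.0):
    """Poisson counts drawn at the state's own means."""
    from hbfm import compute_mean

    r = np.random.default_rng(seed)
    return ExpressionCounts(r.poisson(compute_mean(state) * scale))


@pytest.fixture
def toy_state():
    return make_state()


@pytest.fixture
def toy_counts(toy_state):
    return counts_from_state(toy_state)
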