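import numpy as np
import pytest

from sifinet.synthetic import GroundTruthNetwork, default_source_network


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def source_net() -> GroundTruthNetwork:
    return default_source_network()


@pytest.fixture
def two_node_net() -> GroundTruthNetwork:
    """1 -> 2 coupling at delay 5, strength 0.5."""
    return GroundTruthNetwork(n_nodes=2, links=[(0, 1, 0.5, 5)],
                              self_coefficients=0.5)


def ar1_driven_pair(c: float, seed: int, n_trials: int = 60,
                    n_samples: int = 300, delay: int = 5, a: float = 0.5):
    """y_t = a*y_{t-1} + c*x_{t-delay} + eps with white-noise x.

    The closed-form Gaussian transfer entropy of this system at the
    matched lag is 0.5 * log(1 + c**2) (unit-variance x and eps).
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_trials, n_samples))
    eps = rng.standard_normal((n_trials, n_samples))
    y = np.zeros((n_trials, n_samples))
    for t in range(1, n_samples):
        y[:, t] = a * y[:, t - 1] + eps[:, t]
        if t >= delay:
            y[:, t] += c * x[:, t - delay]
    return x, y


def gaussian_te_closed_form(c: float) -> float:
    return 0.5 * np.log(1.0 + c * c)


def expected_artifact_links(net: GroundTruthNetwork) -> set:
    """Links a bivariate analysis may report without being generative.

    Two-step cascades (X->Y->Z suggests X->Z) and common drives (X->Y,
    X->Z suggests Y->Z or Z->Y); the pruning stage exists to remove
    them, so structure-recovery scores exclude them from the
    false-positive count.
    """
    names = net.node_names
    true_links = {(names[s], names[t]) for s, t, _, _ in net.links}
    children: dict = {}
    for s, t, _, _ in net.links:
        children.setdefault(s, []).append(t)
    artifacts = set()
    for s, t, _, _ in net.links:
        for t2 in children.get(t, []):
            if t2 != s:
                artifacts.add((names[s], names[t2]))
    for _, kids in children.items():
        for y in kids:
            for z in kids:
                if y != z:
                    artifacts.add((names[y], names[z]))
    return artifacts - true_links
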