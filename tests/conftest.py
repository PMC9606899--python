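import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def sklearn_mi_bits(x, y):
    """Independent MI oracle: sklearn's contingency-based estimate, in bits."""
    from sklearn.metrics import mutual_info_score

    return mutual_info_score(x, y) / np.log(2)


def naive_mrmr_order(X, y, n_select, n_bins=10, strategy="equal_frequency"):
    """From-scratch reference selector: no cache, MI recomputed every step via
    sklearn's estimator. First pick maximizes relevance; later picks maximize
    relevance minus mean MI against the selected set; ties break to the lowest
    feature index."""
    from mrmrkit.mi import DiscretizationConfig, discretize

    cfg = DiscretizationConfig(n_bins=n_bins, strategy=strategy)
    codes = [discretize(X[:, j], cfg) for j in range(X.shape[1])]
    _, yc = np.unique(y, return_inverse=True)
    selected, remaining = [], list(range(X.shape[1]))
    while remaining and len(selected) < n_select:
        scores = []
        for j in remaining:
            rel = sklearn_mi_bits(codes[j], yc)
            if selected:
                rel -= np.mean([sklearn_mi_bits(codes[i], codes[j]) for i in selected])
            scores.append(rel)
        top = max(scores)
        best = next(j for j, s in zip(remaining, scores) if s >= top - 1e-9)
        selected.append(best)
        remaining.remove(best)
    return selected


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_table(rng, n=None, m=None):
    """Small random continuous table with random binary/ternary labels."""
    n = n or int(rng.integers(20, 61))
    m = m or int(rng.integers(2, 16))
    X = rng.standard_normal((n, m))
    k = int(rng.integers(2, 4))
    y = rng.integers(0, k, size=n)
    while len(np.unique(y)) < 2:  # guard degenerate draw
        y = rng.integers(0, k, size=n)
    return X, y
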