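"""Plug-in mutual information and entropy on discretized features.

Everything here works in **bits** (log base 2). Continuous feature columns are
discretized first (equal-frequency by default); integer class labels are used
as-is. The estimator is the maximum-likelihood ("plug-in") estimate from the
joint histogram, which carries a small positive bias at small sample sizes —
acceptable here because mutual information enters only through argmax
comparisons and subset averages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DiscretizationConfig",
    "entropy",
    "mutual_information",
    "discretize",
    "MICache",
    "build_cache",
]


@dataclass(frozen=True)
class DiscretizationConfig:
    """How continuous columns are turned into category codes.

    Parameters
    ----------
    n_bins : int
        Target number of bins, >= 2. A constant column always collapses to a
        single category regardless of this value.
    strategy : {"equal_frequency", "equal_width"}
        ``equal_frequency`` assigns codes by quantile rank (duplicate quantile
        edges merged); ``equal_width`` uses uniform intervals over [min, max].
    """

    n_bins: int = 10
    strategy: str = "equal_frequency"

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError(f"n_bins must be >= 2, got {self.n_bins}")
        if self.strategy not in ("equal_frequency", "equal_width"):
            raise ValueError(f"unknown discretization strategy {self.strategy!r}")


def _as_codes(x) -> np.ndarray:
    x = np.asarray(x)
    if x.size == 0:
        raise ValueError("empty vector")
    codes = x.astype(np.int64)
    if np.any(codes < 0):
        raise ValueError("category codes must be non-negative integers")
    return codes.ravel()


def entropy(x) -> float:
    """Plug-in Shannon entropy H(x) in bits, with 0*log(0) == 0."""
    codes = _as_codes(x)
    counts = np.bincount(codes)
    p = counts[counts > 0] / codes.size
    # fsum: exactly rounded, so the value is independent of summation order
    return max(0.0, math.fsum(-pi * np.log2(pi) for pi in p))


def mutual_information(x, y) -> float:
    """Plug-in mutual information I(x;y) in bits from the joint histogram.

    Computed with an exactly rounded sum (fsum), so I(x;y) == I(y;x)
    bit-for-bit. Tiny negative values from rounding are clamped to 0.
    """
    xc, yc = _as_codes(x), _as_codes(y)
    if xc.size != yc.size:
        raise ValueError(f"length mismatch: {xc.size} vs {yc.size}")
    n = xc.size
    nx, ny = int(xc.max()) + 1, int(yc.max()) + 1
    joint = np.zeros((nx, ny))
    np.add.at(joint, (xc, yc), 1.0)
    joint /= n
    # marginals from bincount (not axis sums) so I(x;y) == I(y;x) bit-for-bit
    px = np.bincount(xc, minlength=nx) / n
    py = np.bincount(yc, minlength=ny) / n
    ii, jj = np.nonzero(joint)
    mi = math.fsum(joint[i, j] * np.log2(joint[i, j] / (px[i] * py[j]))
                   for i, j in zip(ii, jj))
    return max(0.0, mi)


def discretize(column, config: DiscretizationConfig = DiscretizationConfig()) -> np.ndarray:
    """Map a numeric column to integer category codes per ``config``.

    Returns at most ``config.n_bins`` categories; a constant column maps to a
    single all-zero category. NaN or infinite values are rejected.
    """
    col = np.asarray(column, dtype=float).ravel()
    if col.size == 0:
        raise ValueError("empty column")
    if not np.all(np.isfinite(col)):
        raise ValueError("column contains NaN or infinite values")
    lo, hi = col.min(), col.max()
    if lo == hi:
        return np.zeros(col.size, dtype=np.int64)
    if config.strategy == "equal_frequency":
        qs = np.linspace(0, 1, config.n_bins + 1)[1:-1]
        edges = np.unique(np.quantile(col, qs))
        codes = np.searchsorted(edges, col, side="left")
    else:  # equal_width
        edges = np.linspace(lo, hi, config.n_bins + 1)[1:-1]
        codes = np.searchsorted(edges, col, side="right")
    # re-densify codes so categories are 0..K-1 with no gaps
    _, codes = np.unique(codes, return_inverse=True)
    return codes.astype(np.int64)


@dataclass
class MICache:
    """Relevance vector I(x_j; c) plus a lazily filled pairwise MI matrix.

    ``relevance[j]`` is eager; ``pairwise(i, j)`` memoizes I(x_i; x_j) so each
    unordered pair is computed at most once. The diagonal is the feature
    entropy, by the identity I(x; x) = H(x).
    """

    codes: np.ndarray  # (m, n) discretized feature rows
    relevance: np.ndarray  # (m,) I(x_j; c) in bits
    _pairwise: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        m = self.codes.shape[0]
        if self._pairwise is None:
            self._pairwise = np.full((m, m), np.nan)

    @property
    def n_features(self) -> int:
        return self.codes.shape[0]

    def pairwise(self, i: int, j: int) -> float:
        """Memoized I(x_i; x_j) in bits (symmetric)."""
        if np.isnan(self._pairwise[i, j]):
            v = mutual_information(self.codes[i], self.codes[j])
            self._pairwise[i, j] = self._pairwise[j, i] = v
        return float(self._pairwise[i, j])

    def redundancy_matrix(self) -> np.ndarray:
        """Fully materialized symmetric pairwise matrix (fills every entry)."""
        m = self.n_features
        for i in range(m):
            for j in range(i, m):
                self.pairwise(i, j)
        return self._pairwise.copy()


def build_cache(features, labels, config: DiscretizationConfig = DiscretizationConfig()) -> MICache:
    """Discretize an (n, m) feature matrix and populate relevance eagerly.

    ``labels`` must already be integer category codes; they are never re-binned.
    Discretization failures are re-raised with the offending column attached.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D matrix")
    y = _as_codes(labels)
    if y.size != X.shape[0]:
        raise ValueError("labels length does not match number of instances")
    codes = np.empty((X.shape[1], X.shape[0]), dtype=np.int64)
    for j in range(X.shape[1]):
        try:
            codes[j] = discretize(X[:, j], config)
        except ValueError as e:
            raise ValueError(f"column {j}: {e}") from e
    relevance = np.array([mutual_information(codes[j], y) for j in range(X.shape[1])])
    return MICache(codes=codes, relevance=relevance)
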