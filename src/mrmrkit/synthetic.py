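"""Seeded synthetic benchmarks with planted ground truth.

Two generators make every other module testable offline:

* ``generate_table`` — labelled feature tables with class-informative
  ("relevant") Gaussian columns, noise-corrupted correlated copies of each
  relevant column ("redundant"), and label-independent noise columns. This
  emulates the statistical structure of a deep-network feature table —
  informative dimensions, near-duplicates, dead units — not its marginal
  distributions.
* ``generate_phantom`` — chest-like image phantoms: a dark background, two
  brighter elliptical "lung" regions, and small bright circular "nodules"
  inside them, with exact ground-truth masks.

All randomness flows from a single integer seed per artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .selection import FeatureTable

__all__ = ["TableSpec", "PhantomSpec", "generate_table", "generate_phantom"]


@dataclass(frozen=True)
class TableSpec:
    """Planted-structure feature table.

    Relevant columns are class-conditional Gaussians with unit variance and
    class means ``effect_size`` apart (a standardized shift). Each redundant
    copy is ``rho * parent + sqrt(1 - rho^2) * eps`` with independent standard
    normal eps, so corr(copy, parent) ~ rho. Noise columns are standard normal,
    independent of the label.
    """

    n_instances: int = 1000
    n_relevant: int = 5
    copies_per_relevant: int = 1
    rho: float = 0.95
    n_noise: int = 40
    effect_size: float = 1.5
    n_classes: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.n_instances < 2:
            raise ValueError("n_instances must be >= 2")
        if self.n_relevant < 0 or self.copies_per_relevant < 0 or self.n_noise < 0:
            raise ValueError("feature counts must be non-negative")
        if self.n_relevant + self.n_noise < 1:
            raise ValueError("need at least one feature column")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [-1, 1]")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")

    @property
    def n_features(self) -> int:
        return self.n_relevant * (1 + self.copies_per_relevant) + self.n_noise


def generate_table(spec: TableSpec) -> tuple[FeatureTable, list[str]]:
    """Deterministically generate a table and its ground-truth role vector.

    Roles are ``"relevant:g"`` / ``"copy:g"`` (g = planted group index) and
    ``"noise"``. Columns are ordered parent-then-copies per group, noise last.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_instances
    labels = np.arange(n) % spec.n_classes
    rng.shuffle(labels)

    cols, names, roles = [], [], []
    for g in range(spec.n_relevant):
        parent = rng.standard_normal(n) + spec.effect_size * labels
        cols.append(parent)
        names.append(f"rel{g}")
        roles.append(f"relevant:{g}")
        for c in range(spec.copies_per_relevant):
            eps = rng.standard_normal(n)
            cols.append(spec.rho * parent + np.sqrt(1.0 - spec.rho**2) * eps)
            names.append(f"rel{g}_copy{c}")
            roles.append(f"copy:{g}")
    for j in range(spec.n_noise):
        cols.append(rng.standard_normal(n))
        names.append(f"noise{j}")
        roles.append("noise")

    table = FeatureTable(features=np.column_stack(cols), labels=labels,
                         feature_names=names)
    return table, roles


@dataclass(frozen=True)
class PhantomSpec:
    """Two-lung image phantom.

    ``ellipses`` are (center_row, center_col, semi_axis_rows, semi_axis_cols)
    in pixels; ``nodules`` are (center_row, center_col, radius, intensity).
    Every nodule must lie entirely inside one of the ellipses. Pixel noise is
    additive Gaussian (``noise_sigma``), clipped to [0, 255].
    """

    side: int = 640
    background: int = 20
    lung_level: int = 130
    noise_sigma: float = 8.0
    ellipses: tuple = None
    nodules: tuple = None
    seed: int = 0

    def __post_init__(self):
        if self.side < 16:
            raise ValueError("side must be >= 16")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        s = self.side
        if self.ellipses is None:
            object.__setattr__(self, "ellipses", (
                (0.50 * s, 0.30 * s, 0.34 * s, 0.15 * s),
                (0.50 * s, 0.70 * s, 0.34 * s, 0.15 * s),
            ))
        if self.nodules is None:
            object.__setattr__(self, "nodules", (
                (0.40 * s, 0.30 * s, 0.030 * s, 230),
                (0.62 * s, 0.68 * s, 0.025 * s, 230),
                (0.48 * s, 0.73 * s, 0.020 * s, 230),
            ))


def _ellipse_mask(side: int, cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    rr, cc = np.mgrid[0:side, 0:side]
    return ((rr - cy) / ry) ** 2 + ((cc - cx) / rx) ** 2 <= 1.0


def _disk_mask(side: int, cy: float, cx: float, radius: float) -> np.ndarray:
    rr, cc = np.mgrid[0:side, 0:side]
    return (rr - cy) ** 2 + (cc - cx) ** 2 <= radius**2


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render ``(image, roi_mask, nodule_mask)``; masks exact by construction.

    Raises if any nodule extends outside every ellipse.
    """
    s = spec.side
    roi = np.zeros((s, s), dtype=bool)
    for e in spec.ellipses:
        roi |= _ellipse_mask(s, *e)

    nodule_mask = np.zeros((s, s), dtype=bool)
    img = np.full((s, s), float(spec.background))
    img[roi] = spec.lung_level
    for k, (cy, cx, radius, level) in enumerate(spec.nodules):
        disk = _disk_mask(s, cy, cx, radius)
        if np.any(disk & ~roi):
            raise ValueError(f"nodule {k} extends outside the lung ellipses")
        nodule_mask |= disk
        img[disk] = level

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img, roi, nodule_mask
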