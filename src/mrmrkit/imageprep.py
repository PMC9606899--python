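"""Morphological region-of-interest extraction and grid partitioning.

The ROI chain mirrors a classical lung-field segmentation: threshold the
grayscale image, erode to strip thin artifacts, median-filter for noise
reduction, dilate back, keep the largest connected components (two, for the
two lung fields), and flood-fill interior holes so bright nodules inside the
region stay part of the mask. Coordinates are 0-based, row-major, origin
top-left; cell extents are half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "PrepConfig",
    "GridSpec",
    "binarize",
    "erode",
    "dilate",
    "median_filter",
    "extract_contours",
    "flood_fill_holes",
    "segment_roi",
    "grid_partition",
]

_EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity for components
_FOUR = ndimage.generate_binary_structure(2, 1)  # 4-connectivity for fill


@dataclass(frozen=True)
class PrepConfig:
    """Knobs of the ROI chain.

    threshold : "otsu" or a fixed numeric cut (pixels > value are foreground).
    se_radius : structuring-element radius r; the element is a (2r+1)^2 square.
    median_window : odd window side for the median filter.
    keep_components : number of largest 8-connected components retained.
    """

    threshold: object = "otsu"
    se_radius: int = 1
    median_window: int = 3
    keep_components: int = 2

    def __post_init__(self):
        if self.median_window % 2 == 0 or self.median_window < 3:
            raise ValueError(f"median_window must be odd and >= 3, got {self.median_window}")
        if self.se_radius < 1:
            raise ValueError("se_radius must be >= 1")
        if self.keep_components < 1:
            raise ValueError("keep_components must be >= 1")


@dataclass(frozen=True)
class GridSpec:
    """S x S partition of an image into equal square-count cells."""

    s_grid: int = 8

    def __post_init__(self):
        if self.s_grid < 1:
            raise ValueError("s_grid must be >= 1")


def _check_image(image) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 2 or img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError(f"expected a 2-D image, got shape {img.shape}")
    return img


def _check_mask(mask) -> np.ndarray:
    m = np.asarray(mask)
    if m.ndim != 2:
        raise ValueError(f"expected a 2-D mask, got shape {m.shape}")
    return m.astype(bool)


def binarize(image, config: PrepConfig = PrepConfig()) -> np.ndarray:
    """Foreground mask via Otsu's inter-class-variance threshold (default)
    or a fixed cut; pixels strictly above the threshold are foreground.

    A constant image has no Otsu threshold; it falls back to the fixed
    midpoint 127.5 with a warning.
    """
    img = _check_image(image)
    if config.threshold == "otsu":
        if img.min() == img.max():
            warnings.warn("constant image: Otsu undefined, using fixed midpoint 127.5")
            t = 127.5
        else:
            t = threshold_otsu(img.astype(np.uint8) if img.dtype != np.uint8 else img)
    else:
        t = float(config.threshold)
    return img > t


def _square_se(radius: int) -> np.ndarray:
    return np.ones((2 * radius + 1, 2 * radius + 1), dtype=bool)


def erode(mask, se_radius: int = 1) -> np.ndarray:
    """Binary erosion by a square element; out-of-bounds neighbors count as
    background, so the mask shrinks at the image border."""
    return ndimage.binary_erosion(_check_mask(mask), _square_se(se_radius), border_value=0)


def dilate(mask, se_radius: int = 1) -> np.ndarray:
    """Binary dilation by a square element; out-of-bounds neighbors are 0."""
    return ndimage.binary_dilation(_check_mask(mask), _square_se(se_radius), border_value=0)


def median_filter(image, window: int = 3) -> np.ndarray:
    """Per-pixel median over a window x window neighborhood, reflected edges."""
    img = _check_image(image)
    if window % 2 == 0:
        raise ValueError(f"median window must be odd, got {window}")
    return ndimage.median_filter(img, size=window, mode="reflect")


def _moore_trace(component: np.ndarray) -> list[tuple[int, int]]:
    """Ordered closed boundary path of one connected component
    (Moore-neighbor tracing, clockwise)."""
    H, W = component.shape
    rs, cs = np.nonzero(component)
    start = (int(rs[0]), int(cs[0]))  # topmost, then leftmost
    # clockwise Moore neighborhood: N NE E SE S SW W NW
    dirs = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]

    def fg(r, c):
        return 0 <= r < H and 0 <= c < W and component[r, c]

    path: list[tuple[int, int]] = []
    seen: set = set()
    cur, back = start, 6  # backtrack points west: start is leftmost in its top row
    while (cur, back) not in seen:
        seen.add((cur, back))
        path.append(cur)
        moved = False
        for i in range(1, 9):
            d = (back + i) % 8
            nr, nc = cur[0] + dirs[d][0], cur[1] + dirs[d][1]
            if fg(nr, nc):
                prev_d = (back + i - 1) % 8
                pr, pc = cur[0] + dirs[prev_d][0], cur[1] + dirs[prev_d][1]
                cur = (nr, nc)
                back = dirs.index((pr - nr, pc - nc))
                moved = True
                break
        if not moved:
            break  # isolated pixel
    return path


def extract_contours(mask, keep_components: int = 2):
    """Largest 8-connected components with their ordered boundary paths.

    Returns ``(contours, component_mask)`` where ``contours`` is a list (one
    closed pixel path per retained component, largest first) and
    ``component_mask`` keeps only the retained components. An empty mask
    yields ``([], empty mask)``.
    """
    m = _check_mask(mask)
    labels, n = ndimage.label(m, structure=_EIGHT)
    if n == 0:
        return [], np.zeros_like(m)
    areas = ndimage.sum_labels(m, labels, index=np.arange(1, n + 1))
    order = np.argsort(-areas, kind="stable")[:keep_components]
    kept = np.isin(labels, order + 1)
    contours = [_moore_trace(labels == lab + 1) for lab in order]
    return contours, kept


def flood_fill_holes(mask) -> np.ndarray:
    """Close interior holes: background not 4-connected to the image border
    becomes foreground. Idempotent and extensive."""
    return ndimage.binary_fill_holes(_check_mask(mask), structure=_FOUR)


def segment_roi(image, config: PrepConfig = PrepConfig()):
    """Full ROI chain: binarize, erode, median-filter + re-threshold, dilate,
    keep the largest components, fill holes.

    Returns ``(mask, roi_image)`` — the binary ROI mask and the source image
    masked to it (0 outside). An empty final mask is returned with a warning
    rather than raised.
    """
    img = _check_image(image)
    mask = binarize(img, config)
    mask = erode(mask, config.se_radius)
    smoothed = median_filter(img, config.median_window)
    mask &= binarize(smoothed, config)
    mask = dilate(mask, config.se_radius)
    _, mask = extract_contours(mask, config.keep_components)
    mask = flood_fill_holes(mask)
    if not mask.any():
        warnings.warn("segment_roi produced an empty mask")
    roi = np.where(mask, img, 0)
    return mask, roi


def grid_partition(image, grid: GridSpec = GridSpec()):
    """Tile the image into s_grid x s_grid cells with half-open pixel extents.

    Returns a list of dicts ``{"row", "col", "extent": (r0, r1, c0, c1),
    "view": ndarray}`` covering the image exactly, no overlap. Each side must
    be divisible by ``s_grid``.
    """
    img = _check_image(image)
    H, W = img.shape
    s = grid.s_grid
    if H % s:
        raise ValueError(f"image height {H} not divisible by grid {s}")
    if W % s:
        raise ValueError(f"image width {W} not divisible by grid {s}")
    ch, cw = H // s, W // s
    cells = []
    for r in range(s):
        for c in range(s):
            r0, c0 = r * ch, c * cw
            cells.append({
                "row": r, "col": c,
                "extent": (r0, r0 + ch, c0, c0 + cw),
                "view": img[r0:r0 + ch, c0:c0 + cw],
            })
    return cells
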