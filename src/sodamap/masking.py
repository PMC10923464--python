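"""Cell-mask extraction by K-class intensity K-means thresholding.

A counterstain channel (e.g. a somato-dendritic MAP2 stain) is reduced to a
binary occupancy mask in three steps: (1) 1D K-means (Lloyd) on a 256-bin
intensity histogram yields K-1 thresholds; (2) voxels above the threshold
selected by ``foreground_classes`` are kept and connected components
outside the size bounds are removed; (3) morphological closing fills small
holes and gaps.  Running K-means on the histogram rather than per voxel
makes the result deterministic and invariant to affine intensity rescaling.

The hierarchical variant sweeps K upward and keeps the smallest K whose
largest foreground component falls inside the size bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import ball, disk

from .io import CellMask

__all__ = [
    "HKParams",
    "kmeans_intensity_thresholds",
    "segment_cell_mask",
    "hierarchical_segment_cell_mask",
]

_N_BINS = 256


@dataclass
class HKParams:
    n_classes: int = 3
    foreground_classes: int | None = None  # default K - 1
    min_size_px: int = 50
    max_size_px: float = math.inf
    dilation_px: int = 2

    def __post_init__(self) -> None:
        if not 2 <= self.n_classes <= 10:
            raise ValueError("n_classes must be in [2, 10]")
        if self.foreground_classes is None:
            self.foreground_classes = self.n_classes - 1
        if not 1 <= self.foreground_classes < self.n_classes:
            raise ValueError("foreground_classes must be in [1, n_classes)")
        if self.min_size_px < 0 or self.max_size_px < self.min_size_px:
            raise ValueError("invalid size bounds")
        if self.dilation_px < 0:
            raise ValueError("dilation_px must be >= 0")


def kmeans_intensity_thresholds(channel: np.ndarray, n_classes: int) -> np.ndarray:
    """K-class Lloyd K-means on the 256-bin intensity histogram.

    Centroids are initialised at equally spaced quantiles of the intensity
    distribution (deterministic), iterated to convergence (cap 100
    iterations, tolerance 1e-6 of the intensity range on centroid motion),
    and the K-1 thresholds returned are the midpoints between adjacent
    sorted centroids.

    Raises ``ValueError("degenerate histogram")`` when the channel has fewer
    than ``n_classes`` distinct values.
    """
    vals = np.asarray(channel, dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("degenerate histogram")
    lo, hi = float(vals.min()), float(vals.max())
    if np.unique(vals).size < n_classes:
        raise ValueError("degenerate histogram")

    counts, edges = np.histogram(vals, bins=_N_BINS, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    occupied = counts > 0
    centers_o, counts_o = centers[occupied], counts[occupied].astype(float)

    q = (2 * np.arange(n_classes) + 1) / (2 * n_classes)
    centroids = np.quantile(vals, q)
    # quantile init can collide on spiky histograms; spread duplicates
    for i in range(1, n_classes):
        if centroids[i] <= centroids[i - 1]:
            centroids[i] = centroids[i - 1] + (hi - lo) / (10 * _N_BINS) + 1e-12

    tol = 1e-6 * max(hi - lo, 1.0)
    for _ in range(100):
        assign = np.argmin(np.abs(centers_o[:, None] - centroids[None, :]), axis=1)
        new = centroids.copy()
        for k in range(n_classes):
            sel = assign == k
            if sel.any():
                new[k] = np.average(centers_o[sel], weights=counts_o[sel])
        if np.max(np.abs(new - centroids)) <= tol:
            centroids = new
            break
        centroids = new
    centroids = np.sort(centroids)
    return 0.5 * (centroids[:-1] + centroids[1:])


def _size_filter(fg: np.ndarray, min_size: int, max_size: float) -> np.ndarray:
    structure = np.ones((3,) * fg.ndim, dtype=bool)
    labels, n_lab = ndimage.label(fg, structure=structure)
    if n_lab == 0:
        return fg
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    keep = (sizes >= min_size) & (sizes <= max_size)
    return keep[labels]


def _close(fg: np.ndarray, radius: int) -> np.ndarray:
    if radius <= 0 or not fg.any():
        return fg
    footprint = disk(radius) if fg.ndim == 2 else ball(radius)
    return ndimage.binary_closing(fg, structure=footprint)


def segment_cell_mask(
    channel: np.ndarray,
    params: HKParams | None = None,
    pixel_size: float | tuple[float, ...] = 100.0,
) -> CellMask:
    """Segment the cell mask from a counterstain channel.

    Voxels above the ``(K - foreground_classes)``-th threshold (1-based in
    the sorted threshold list) are foreground; components outside
    ``[min_size_px, max_size_px]`` are removed; the mask is closed with
    radius ``dilation_px``.  Raises ``ValueError("no cell found")`` when
    nothing survives.
    """
    params = params or HKParams()
    grid = np.asarray(channel, dtype=float)
    thresholds = kmeans_intensity_thresholds(grid, params.n_classes)
    thr = thresholds[params.n_classes - 1 - params.foreground_classes]
    fg = grid > thr
    fg = _size_filter(fg, params.min_size_px, params.max_size_px)
    fg = _close(fg, params.dilation_px)
    if not fg.any():
        raise ValueError("no cell found")
    return CellMask(fg, pixel_size=pixel_size)


def hierarchical_segment_cell_mask(
    channel: np.ndarray,
    params: HKParams | None = None,
    pixel_size: float | tuple[float, ...] = 100.0,
) -> CellMask:
    """K-sweep variant: smallest K in [2, n_classes] whose largest
    foreground component lies inside the size bounds; falls back to
    ``n_classes`` when no K qualifies."""
    params = params or HKParams()
    grid = np.asarray(channel, dtype=float)
    chosen = None
    for k in range(2, params.n_classes + 1):
        p_k = HKParams(
            n_classes=k,
            foreground_classes=min(params.foreground_classes, k - 1),
            min_size_px=params.min_size_px,
            max_size_px=params.max_size_px,
            dilation_px=params.dilation_px,
        )
        try:
            thresholds = kmeans_intensity_thresholds(grid, k)
        except ValueError:
            continue
        thr = thresholds[k - 1 - p_k.foreground_classes]
        fg = grid > thr
        structure = np.ones((3,) * fg.ndim, dtype=bool)
        labels, n_lab = ndimage.label(fg, structure=structure)
        if n_lab == 0:
            continue
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        largest = sizes.max()
        if params.min_size_px <= largest <= params.max_size_px:
            chosen = p_k
            break
    if chosen is None:
        chosen = params
    return segment_cell_mask(grid, chosen, pixel_size=pixel_size)
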