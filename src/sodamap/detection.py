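"""Spot detection by undecimated a-trous wavelet filtering.

The input channel is decomposed with the separable B3-spline kernel
``(1/16, 1/4, 3/8, 1/4, 1/16)``; at scale ``s`` the kernel is dilated by
inserting ``2**(s-1) - 1`` zeros between taps ("a trous" = with holes).
With ``A_0`` the input and ``A_s = A_{s-1} * kernel_s`` (mirror boundary),
the detail planes are ``W_s = A_{s-1} - A_s`` and the decomposition
reconstructs exactly: ``sum_s W_s + A_S == A_0``.

Spot-sized structures concentrate in the low scales (plane 2 for spots of
roughly 2-6 px diameter), so detection thresholds the selected detail
planes at ``k_sigma`` times a robust noise level (median absolute
deviation / 0.6745) and keeps connected components of sufficient size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import CellMask, SpotSet

__all__ = ["WaveletPlanes", "DetectionParams", "atrous_wavelet", "detect_spots"]

#: B3-spline scaling kernel.
B3_KERNEL = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


@dataclass
class WaveletPlanes:
    """Detail planes ``W_1..W_S`` plus the smooth residual ``A_S``."""

    planes: list[np.ndarray]
    residual: np.ndarray

    @property
    def n_scales(self) -> int:
        return len(self.planes)

    def reconstruct(self) -> np.ndarray:
        return sum(self.planes) + self.residual


@dataclass
class DetectionParams:
    """Tunable spot-detector parameters.

    ``scales`` are the detail planes that must all exceed threshold
    (default ``{2}``); ``k_sigma`` multiplies the per-plane robust noise
    estimate; components smaller than ``min_size_px`` pixels are dropped.
    """

    scales: frozenset[int] = field(default_factory=lambda: frozenset({2}))
    k_sigma: float = 3.0
    min_size_px: int = 2

    def __post_init__(self) -> None:
        self.scales = frozenset(int(s) for s in self.scales)
        if not self.scales or min(self.scales) < 1:
            raise ValueError("scales must be a nonempty set of indices >= 1")
        if self.k_sigma <= 0:
            raise ValueError("k_sigma must be positive")
        if self.min_size_px < 1:
            raise ValueError("min_size_px must be >= 1")


def _dilated_kernel(scale: int) -> np.ndarray:
    """B3 kernel with ``2**(scale-1) - 1`` zeros inserted between taps."""
    step = 2 ** (scale - 1)
    kernel = np.zeros(4 * step + 1)
    kernel[::step] = B3_KERNEL
    return kernel


def atrous_wavelet(image_channel: np.ndarray, n_scales: int) -> WaveletPlanes:
    """Undecimated a-trous decomposition of a 2D/3D grid into ``n_scales`` planes.

    Raises if the dilated kernel support at the deepest scale exceeds what
    the grid extent can support with mirror boundary handling.
    """
    if n_scales < 1:
        raise ValueError("n_scales must be >= 1")
    grid = np.asarray(image_channel, dtype=float)
    if grid.ndim not in (2, 3):
        raise ValueError("expected a 2D or 3D grid")
    support = 4 * 2 ** (n_scales - 1) + 1
    if support // 2 + 1 > min(grid.shape):
        raise ValueError(
            f"scale {n_scales} kernel support ({support}) exceeds grid extent {grid.shape}"
        )
    planes: list[np.ndarray] = []
    approx = grid
    for s in range(1, n_scales + 1):
        kernel = _dilated_kernel(s)
        smooth = approx
        for axis in range(grid.ndim):
            smooth = ndimage.correlate1d(smooth, kernel, axis=axis, mode="mirror")
        planes.append(approx - smooth)
        approx = smooth
    return WaveletPlanes(planes=planes, residual=approx)


def detect_spots(
    image_channel: np.ndarray,
    params: DetectionParams | None = None,
    pixel_size: float | tuple[float, ...] = 100.0,
    mask: CellMask | None = None,
    channel_id: str = "",
) -> SpotSet:
    """Detect spots in one channel and return their sub-pixel centroids.

    For every selected scale ``s`` the robust noise level is
    ``sigma_s = median(|W_s|) / 0.6745`` (estimated inside the mask when one
    is given); a voxel is kept when ``W_s > k_sigma * sigma_s`` for ALL
    selected scales.  Kept voxels are grouped with full (8/26) connectivity,
    components below ``min_size_px`` are dropped, and each remaining
    component becomes one spot at its intensity-weighted centroid (weights =
    original channel values), converted to nm.  Spots whose centroid falls
    outside the mask are discarded.  An all-zero image yields an empty
    SpotSet.
    """
    params = params or DetectionParams()
    grid = np.asarray(image_channel, dtype=float)
    if grid.size == 0:
        raise ValueError("empty grid")
    ndim = grid.ndim
    px = np.atleast_1d(np.asarray(pixel_size, dtype=float))
    if px.size == 1:
        px = np.repeat(px, ndim)

    n_scales = max(params.scales)
    wp = atrous_wavelet(grid, n_scales)

    if mask is not None:
        if mask.grid.shape != grid.shape:
            raise ValueError("mask geometry does not match the channel")
        region = mask.grid
    else:
        region = None

    keep = np.ones(grid.shape, dtype=bool)
    for s in params.scales:
        w = wp.planes[s - 1]
        sample = w[region] if region is not None else w
        sigma = float(np.median(np.abs(sample))) / 0.6745
        keep &= w > params.k_sigma * sigma
    if not keep.any():
        return SpotSet(np.empty((0, ndim)), channel_id=channel_id)

    structure = np.ones((3,) * ndim, dtype=bool)
    labels, n_lab = ndimage.label(keep, structure=structure)
    if n_lab == 0:
        return SpotSet(np.empty((0, ndim)), channel_id=channel_id)
    ids = np.arange(1, n_lab + 1)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, ids)
    ok = sizes >= params.min_size_px
    ids, sizes = ids[ok], sizes[ok]
    if ids.size == 0:
        return SpotSet(np.empty((0, ndim)), channel_id=channel_id)

    # intensity-weighted centroid on the original channel; fall back to the
    # geometric centroid where a component has zero total intensity
    weights = np.clip(grid, 0.0, None)
    totals = ndimage.sum_labels(weights, labels, ids)
    centroids = np.empty((ids.size, ndim))
    flat_ok = totals > 0
    if flat_ok.any():
        com = ndimage.center_of_mass(weights, labels, ids[flat_ok])
        centroids[flat_ok] = np.asarray(com, dtype=float).reshape(-1, ndim)
    if (~flat_ok).any():
        com = ndimage.center_of_mass(keep.astype(float), labels, ids[~flat_ok])
        centroids[~flat_ok] = np.asarray(com, dtype=float).reshape(-1, ndim)

    positions = (centroids + 0.5) * px
    intensities = ndimage.sum_labels(grid, labels, ids)
    spots = SpotSet(positions, intensities, sizes.astype(float), channel_id=channel_id)
    if mask is not None and spots.n:
        spots = spots.subset(mask.contains(spots.positions))
    return spots
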