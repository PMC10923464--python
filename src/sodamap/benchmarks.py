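"""Calibration benchmarks on synthetic ground truth.

These run the full method on simulated scenarios with known parameters and
measure how well it behaves: type-I error under complete spatial
randomness, recovery of the coupled fraction and coupling distance,
detection recall/precision on rendered images, and mask-segmentation IoU.
They are used both by the test suite and by the reproduction script.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .coupling import RingSpec, run_soda
from .detection import DetectionParams, detect_spots
from .masking import HKParams, hierarchical_segment_cell_mask
from .simulate import SimScenario, render_image, simulate_patterns

__all__ = [
    "type_one_error",
    "parameter_recovery",
    "detection_benchmark",
    "mask_benchmark",
]


def _run_scenario(sc: SimScenario, rings: RingSpec, alpha: float, resamples: int):
    mask, s1, s2, _ = simulate_patterns(sc)
    return run_soda(
        s1, s2, mask, rings=rings, alpha=alpha,
        n_resamples=resamples, seed=sc.seed + 1,
    )


def type_one_error(
    n_seeds: int = 200,
    n_per_channel: int = 300,
    alpha: float = 0.05,
    resamples: int = 200,
    seed0: int = 0,
    shape: tuple[int, int] = (100, 100),
) -> dict:
    """Global rejection rate under CSR (coupled fraction 0).

    The edge-corrected null is well calibrated when the rate sits near
    ``alpha``.  Returns the rate and the per-seed p-values.
    """
    rings = RingSpec.uniform(30.0, 10)
    pvals = np.empty(n_seeds)
    base = SimScenario(
        shape=shape, n1=n_per_channel, n2=n_per_channel, coupled_fraction=0.0
    )
    for k in range(n_seeds):
        sc = replace(base, seed=seed0 + k)
        _, result = _run_scenario(sc, rings, alpha, resamples)
        pvals[k] = result.p_value
    return {
        "rate": float(np.mean(pvals < alpha)),
        "p_values": pvals,
        "n_seeds": n_seeds,
        "alpha": alpha,
    }


def parameter_recovery(
    fractions: tuple[float, ...] = (0.2, 0.5, 0.8),
    distances: tuple[float, ...] = (30.0, 80.0),
    n_seeds: int = 10,
    n_per_channel: int = 300,
    jitter_sd_nm: float = 10.0,
    alpha: float = 0.05,
    resamples: int = 200,
    seed0: int = 0,
) -> pd.DataFrame:
    """Recover (q, d_c) over a grid of coupled scenarios.

    One row per run: true and recovered coupled fraction (channel-2
    convention, since q is the fraction of channel-2 spots coupled), the
    probability-weighted mean distance, and the expected couple count.
    """
    rings = RingSpec.uniform(30.0, 10)
    rows = []
    for q in fractions:
        for d_c in distances:
            for k in range(n_seeds):
                sc = SimScenario(
                    n1=n_per_channel,
                    n2=n_per_channel,
                    coupled_fraction=q,
                    coupling_distance_nm=d_c,
                    jitter_sd_nm=jitter_sd_nm,
                    seed=seed0 + k,
                )
                _, result = _run_scenario(sc, rings, alpha, resamples)
                rows.append(
                    {
                        "q": q,
                        "d_c": d_c,
                        "seed": sc.seed,
                        "recovered_fraction": result.coupling_fraction_ch2,
                        "mu_d": result.mean_distance,
                        "n_coupled": result.n_coupled,
                        "p_value": result.p_value,
                    }
                )
    return pd.DataFrame(rows)


def match_detections(
    truth: np.ndarray, detected: np.ndarray, radius: float
) -> tuple[int, int, int]:
    """Greedy one-to-one matching by distance; returns (matched, n_truth, n_det)."""
    n_t, n_d = len(truth), len(detected)
    if n_t == 0 or n_d == 0:
        return 0, n_t, n_d
    tree = cKDTree(detected)
    pairs = []
    for ti, pos in enumerate(truth):
        for di in tree.query_ball_point(pos, radius):
            pairs.append((float(np.linalg.norm(pos - detected[di])), ti, di))
    pairs.sort()
    used_t: set[int] = set()
    used_d: set[int] = set()
    matched = 0
    for _, ti, di in pairs:
        if ti in used_t or di in used_d:
            continue
        used_t.add(ti)
        used_d.add(di)
        matched += 1
    return matched, n_t, n_d


def detection_benchmark(
    seed: int = 0,
    n_spots: int = 40,
    match_radius_px: float = 3.0,
) -> dict:
    """Spot-detector recall/precision on a rendered high-SNR scenario.

    Spots are kept at least 6 px apart; the rendered peak-to-background
    noise ratio is well above 5.
    """
    sc = SimScenario(
        shape=(128, 128),
        n1=n_spots,
        n2=0,
        coupled_fraction=0.0,
        min_separation_nm=600.0,
        psf_sigma_px=1.5,
        photon_scale=800.0,
        background_rate=10.0,
        seed=seed,
    )
    mask, s1, _, _ = simulate_patterns(sc)
    img = render_image(mask, (s1,), sc)
    spots = detect_spots(img.channel("ch1"), DetectionParams(), img.pixel_size)
    radius_nm = match_radius_px * sc.pixel_size_nm
    matched, n_t, n_d = match_detections(s1.positions, spots.positions, radius_nm)
    return {
        "recall": matched / n_t if n_t else float("nan"),
        "precision": matched / n_d if n_d else 0.0,
        "n_truth": n_t,
        "n_detected": n_d,
    }


def mask_benchmark(seed: int = 0, shape: tuple[int, int] = (128, 128)) -> dict:
    """Segmentation IoU on a noisy bright disk of known geometry."""
    rng = np.random.default_rng(seed)
    yy, xx = np.indices(shape)
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    true_disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= 20.0**2
    image = np.where(true_disk, 200.0, 10.0) + rng.normal(0.0, 5.0, shape)
    image = np.clip(image, 0.0, None)
    mask = hierarchical_segment_cell_mask(image, HKParams(), pixel_size=100.0)
    inter = np.logical_and(mask.grid, true_disk).sum()
    union = np.logical_or(mask.grid, true_disk).sum()
    return {"iou": float(inter / union), "n_pixels": int(true_disk.sum())}
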