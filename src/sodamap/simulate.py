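"""Synthetic ground-truth generator for coupled point patterns and images.

Emulates a two-channel colocalization experiment: a cell-shaped binary
mask, a reference population of channel-1 spots uniform in the mask, and a
channel-2 population of which a known fraction ``q`` is coupled — each
coupled point is placed at distance ``|N(d_c, sigma_c^2)|`` from a randomly
chosen channel-1 partner in a uniform direction (direction resampled until
the point lands inside the mask, so the distance law is preserved
conditional on feasibility).  The remaining channel-2 points are uniform in
the mask.  Optionally the patterns are rendered into a fluorescence image:
each spot becomes a Gaussian point-spread function of integral
``photon_scale x intensity`` over a uniform background, with Poisson shot
noise.

Everything is deterministic given the scenario seed, which makes these
patterns usable both as test fixtures and as calibration benchmarks
(type-I error, parameter recovery, detection quality).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from scipy.spatial import cKDTree

from .io import CellMask, ImageStack, SpotSet

__all__ = ["SimScenario", "make_mask", "simulate_patterns", "render_image", "simulate_batch"]


@dataclass(frozen=True)
class SimScenario:
    """Generative parameters for one synthetic dataset.

    Defaults describe the baseline study condition: a 10 x 10 um rectangle
    window at 100 nm pixels, 300 spots per channel, half the channel-2
    spots coupled at 50 +/- 10 nm.
    """

    shape: tuple[int, ...] = (100, 100)       # grid shape ([Z,] Y, X), pixels
    pixel_size_nm: float = 100.0
    mask_shape: str = "rectangle"             # rectangle | disk | neurite
    n1: int = 300
    n2: int = 300
    coupled_fraction: float = 0.5             # q, fraction of ch2 coupled
    coupling_distance_nm: float = 50.0        # d_c
    jitter_sd_nm: float = 10.0                # sigma_c
    min_separation_nm: float = 0.0            # ch1 hard-core distance (0 = off)
    psf_sigma_px: float = 1.5
    photon_scale: float = 1000.0
    background_rate: float = 10.0
    shot_noise: bool = True
    mask_channel_intensity: float = 60.0
    neurite_steps: int = 500
    neurite_radius_px: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupled_fraction <= 1.0:
            raise ValueError("coupled_fraction must be in [0, 1]")
        if self.coupling_distance_nm < 0 or self.jitter_sd_nm < 0:
            raise ValueError("distances must be nonnegative")
        if self.n1 < 0 or self.n2 < 0:
            raise ValueError("counts must be nonnegative")
        if self.mask_shape not in ("rectangle", "disk", "neurite"):
            raise ValueError(f"unknown mask_shape {self.mask_shape!r}")
        if len(self.shape) not in (2, 3):
            raise ValueError("shape must be 2D or 3D")

    @property
    def dim(self) -> int:
        return len(self.shape)


def make_mask(sc: SimScenario) -> CellMask:
    """Build the scenario's binary mask.

    ``rectangle``: the full grid minus a 2-pixel border.  ``disk``
    (``ball`` in 3D): radius 0.45 x the smallest extent, centred.
    ``neurite``: a seeded lattice random walk dilated to a tube — thin
    curved geometry where edge correction matters.
    """
    shape = sc.shape
    if sc.mask_shape == "rectangle":
        grid = np.zeros(shape, dtype=bool)
        sl = tuple(slice(2, s - 2) for s in shape)
        grid[sl] = True
    elif sc.mask_shape == "disk":
        center = (np.asarray(shape) - 1) / 2.0
        radius = 0.45 * min(shape)
        coords = np.indices(shape)
        r2 = sum((coords[a] - center[a]) ** 2 for a in range(len(shape)))
        grid = r2 <= radius**2
    else:  # neurite
        rng = np.random.default_rng([sc.seed, 9157])
        grid = np.zeros(shape, dtype=bool)
        pos = np.asarray(shape) // 2
        ndim = len(shape)
        for _ in range(sc.neurite_steps):
            grid[tuple(pos)] = True
            step = np.zeros(ndim, dtype=int)
            axis = rng.integers(0, ndim)
            step[axis] = rng.choice([-1, 1])
            pos = np.clip(pos + step, 1, np.asarray(shape) - 2)
        grid = ndimage.binary_dilation(
            grid, iterations=sc.neurite_radius_px, structure=ndimage.generate_binary_structure(ndim, 1)
        )
    return CellMask(grid, pixel_size=sc.pixel_size_nm)


def _uniform_directions(n: int, dim: int, rng: np.random.Generator) -> np.ndarray:
    if dim == 2:
        ang = rng.uniform(0.0, 2.0 * np.pi, n)
        return np.stack([np.sin(ang), np.cos(ang)], axis=1)
    v = rng.normal(size=(n, dim))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _sample_ch1(mask: CellMask, n: int, min_sep: float, rng: np.random.Generator) -> np.ndarray:
    if min_sep <= 0 or n <= 1:
        return mask.sample_uniform(n, rng)
    accepted: list[np.ndarray] = []
    attempts = 0
    while len(accepted) < n:
        attempts += 1
        if attempts > 200 * n:
            raise RuntimeError("could not satisfy min_separation in this mask")
        cand = mask.sample_uniform(1, rng)[0]
        if accepted:
            tree = cKDTree(np.asarray(accepted))
            if tree.query(cand, k=1)[0] < min_sep:
                continue
        accepted.append(cand)
    return np.asarray(accepted)


def simulate_patterns(
    sc: SimScenario,
) -> tuple[CellMask, SpotSet, SpotSet, pd.DataFrame]:
    """Generate (mask, ch1 spots, ch2 spots, truth table) for a scenario.

    The truth table has one row per channel-2 spot: ``partner`` is the
    index of its channel-1 partner (-1 for uncoupled spots) and
    ``true_distance_nm`` the drawn pairing distance (NaN for uncoupled).
    """
    rng = np.random.default_rng(sc.seed)
    mask = make_mask(sc)
    p1 = _sample_ch1(mask, sc.n1, sc.min_separation_nm, rng)

    n_coupled = int(round(sc.coupled_fraction * sc.n2))
    if n_coupled > 0 and sc.n1 == 0:
        raise ValueError("cannot couple channel-2 points without channel-1 points")

    coupled = np.empty((n_coupled, sc.dim))
    partners = (
        rng.integers(0, sc.n1, n_coupled) if n_coupled else np.empty(0, dtype=int)
    )
    distances = (
        np.abs(rng.normal(sc.coupling_distance_nm, sc.jitter_sd_nm, n_coupled))
        if n_coupled
        else np.empty(0)
    )
    pending = np.arange(n_coupled)
    rounds = 0
    while pending.size:
        rounds += 1
        dirs = _uniform_directions(pending.size, sc.dim, rng)
        cand = p1[partners[pending]] + distances[pending, None] * dirs
        ok = mask.contains(cand)
        coupled[pending[ok]] = cand[ok]
        pending = pending[~ok]
        if rounds % 200 == 0 and pending.size:
            # distance infeasible from these partners: redraw distance too
            distances[pending] = np.abs(
                rng.normal(sc.coupling_distance_nm, sc.jitter_sd_nm, pending.size)
            )
        if rounds > 5000:
            raise RuntimeError("could not place coupled points inside the mask")

    n_free = sc.n2 - n_coupled
    free = mask.sample_uniform(n_free, rng) if n_free else np.empty((0, sc.dim))
    p2 = np.concatenate([coupled, free], axis=0)

    truth = pd.DataFrame(
        {
            "partner": np.concatenate(
                [partners, -np.ones(n_free, dtype=int)]
            ).astype(int),
            "true_distance_nm": np.concatenate(
                [distances, np.full(n_free, np.nan)]
            ),
        }
    )
    spots1 = SpotSet(p1, channel_id="1")
    spots2 = SpotSet(p2, channel_id="2")
    return mask, spots1, spots2, truth


def render_image(
    mask: CellMask,
    spot_sets: Sequence[SpotSet],
    sc: SimScenario,
    rng: np.random.Generator | None = None,
) -> ImageStack:
    """Render 2D point patterns into a fluorescence image stack.

    One channel per spot set, each spot splatted as a Gaussian PSF with
    integral ``photon_scale x intensity``, plus a uniform Poisson
    background; a final channel carries the mask counterstain
    (``mask_channel_intensity`` inside the cell).  Seeded via the scenario
    unless an explicit generator is passed.
    """
    if mask.dim != 2:
        raise ValueError("image rendering is 2D only")
    if rng is None:
        rng = np.random.default_rng([sc.seed, 31])
    shape = mask.grid.shape
    px = np.asarray(mask.pixel_size)
    sigma = sc.psf_sigma_px
    half = max(1, int(math.ceil(4.0 * sigma)))
    channels: list[np.ndarray] = []
    for spots in spot_sets:
        canvas = np.zeros(shape, dtype=float)
        if sc.photon_scale > 0:
            for pos, inten in zip(spots.positions, spots.intensities):
                cy, cx = pos / px  # sub-pixel centre in index space, minus the 0.5 offset
                cy -= 0.5
                cx -= 0.5
                y0, y1 = max(0, int(cy) - half), min(shape[0], int(cy) + half + 1)
                x0, x1 = max(0, int(cx) - half), min(shape[1], int(cx) + half + 1)
                if y0 >= y1 or x0 >= x1:
                    continue
                yy, xx = np.mgrid[y0:y1, x0:x1]
                g = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma**2))
                canvas[y0:y1, x0:x1] += (
                    sc.photon_scale * inten / (2.0 * np.pi * sigma**2)
                ) * g
        canvas += sc.background_rate
        channels.append(rng.poisson(canvas).astype(float) if sc.shot_noise else canvas)
    counterstain = sc.background_rate + sc.mask_channel_intensity * mask.grid
    channels.append(
        rng.poisson(counterstain).astype(float) if sc.shot_noise else counterstain.astype(float)
    )
    names = [f"ch{i + 1}" for i in range(len(spot_sets))] + ["mask"]
    return ImageStack(np.stack(channels), pixel_size=mask.pixel_size, channel_names=names)


def _scenario_record(sc: SimScenario) -> dict:
    rec = {}
    for f in fields(sc):
        v = getattr(sc, f.name)
        rec[f.name] = "x".join(str(s) for s in v) if isinstance(v, tuple) else v
    return rec


def simulate_batch(
    scenarios: Iterable[SimScenario], out_dir: str | Path
) -> pd.DataFrame:
    """Write a fixture folder: per scenario a localization CSV, a truth CSV,
    a binary mask TIFF and (2D) a rendered image TIFF, plus ``manifest.csv``
    recording every generative parameter.  Rerunning with the same
    scenarios reproduces byte-identical CSVs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = []
    for idx, sc in enumerate(scenarios):
        sid = f"sim{idx:03d}"
        mask, s1, s2, truth = simulate_patterns(sc)
        axes = ["z", "y", "x"][-sc.dim:]
        rows = []
        for ch, spots in (("1", s1), ("2", s2)):
            df = pd.DataFrame(
                spots.positions, columns=[f"{a} [nm]" for a in axes]
            )
            df.insert(0, "channel", ch)
            rows.append(df)
        locs = pd.concat(rows, ignore_index=True)
        # fixed order x, y[, z] after the channel column (ThunderSTORM-like)
        locs = locs[["channel"] + [f"{a} [nm]" for a in reversed(axes)]]
        loc_path = out / f"{sid}_locs.csv"
        locs.to_csv(loc_path, index=False, float_format="%.6f")
        truth_path = out / f"{sid}_truth.csv"
        truth.to_csv(truth_path, index=False, float_format="%.6f")
        mask_path = out / f"{sid}_mask.tif"
        tifffile.imwrite(mask_path, mask.grid.astype(np.uint8))
        img_path = ""
        if sc.dim == 2:
            img = render_image(mask, (s1, s2), sc)
            img_path = f"{sid}_image.tif"
            tifffile.imwrite(
                out / img_path,
                np.clip(img.voxels, 0, 65535).astype(np.uint16),
            )
        rec = _scenario_record(sc)
        rec.update(
            id=sid,
            locs_file=loc_path.name,
            truth_file=truth_path.name,
            mask_file=mask_path.name,
            image_file=img_path,
        )
        records.append(rec)
    manifest = pd.DataFrame(records)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
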