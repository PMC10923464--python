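"""Shared domain types and file I/O.

Coordinate convention
---------------------
All spot positions live in continuous physical space, in nanometres, with
the origin at the corner of pixel ``(0, 0)`` and the centre of pixel ``i``
at ``(i + 0.5) * pixel_size``.  Position arrays are ``(N, D)`` with column
order matching the spatial axes of the image grid: ``(y, x)`` in 2D and
``(z, y, x)`` in 3D.  Grid indices are 0-based.

Supported formats are multichannel TIFF images (2D or 3D), ThunderSTORM-like
localization CSV tables (``x [nm]``, ``y [nm]``, optional ``z [nm]`` and
``channel`` columns), CSV result tables, and PNG association maps.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

__all__ = [
    "ImageStack",
    "SpotSet",
    "CellMask",
    "ResultsTable",
    "RESULT_COLUMNS",
    "RING_COLUMNS",
    "MAP_COLORS",
    "read_image",
    "read_mask_tiff",
    "read_localizations",
    "write_results",
    "render_molecular_map",
    "save_png",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ImageStack:
    """A multichannel fluorescence image: ``voxels`` is ``(C, [Z,] Y, X)``.

    ``pixel_size`` is nm per pixel, one entry per *spatial* axis in grid
    order.  ``channel_names`` labels the channel axis.
    """

    voxels: np.ndarray
    pixel_size: tuple[float, ...]
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim not in (3, 4):
            raise ValueError(
                f"expected (C, Y, X) or (C, Z, Y, X) voxels, got shape {self.voxels.shape}"
            )
        if not np.issubdtype(self.voxels.dtype, np.number):
            raise ValueError("non-numeric pixel data")
        if any(s < 1 for s in self.voxels.shape):
            raise ValueError("all dimensions must be >= 1")
        self.pixel_size = tuple(float(p) for p in np.atleast_1d(self.pixel_size))
        if len(self.pixel_size) == 1:
            self.pixel_size = self.pixel_size * self.ndim_spatial
        if len(self.pixel_size) != self.ndim_spatial:
            raise ValueError("pixel_size must have one entry per spatial axis")
        if any(p <= 0 for p in self.pixel_size):
            raise ValueError("pixel_size must be positive")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.n_channels)]

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[0]

    @property
    def ndim_spatial(self) -> int:
        return self.voxels.ndim - 1

    def channel(self, key: int | str) -> np.ndarray:
        """Spatial grid of one channel, by index or by name."""
        if isinstance(key, str):
            key = self.channel_names.index(key)
        return self.voxels[key]


@dataclass
class SpotSet:
    """A point pattern for one channel: positions (nm) plus marks.

    Marks are per-spot total intensity (arbitrary units) and size in pixels;
    both default to 1, which is the convention for SMLM localizations.
    """

    positions: np.ndarray
    intensities: np.ndarray | None = None
    sizes: np.ndarray | None = None
    channel_id: str = ""

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.size == 0:
            pos = pos.reshape(0, 2 if pos.ndim < 2 else pos.shape[-1])
        if pos.ndim != 2:
            raise ValueError("positions must be (N, D)")
        if pos.shape[0] and pos.shape[1] not in (2, 3):
            raise ValueError(f"dimension must be 2 or 3, got {pos.shape[1]}")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        self.positions = pos
        n = pos.shape[0]
        if self.intensities is None:
            self.intensities = np.ones(n)
        if self.sizes is None:
            self.sizes = np.ones(n)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.sizes = np.asarray(self.sizes, dtype=float)
        if len(self.intensities) != n or len(self.sizes) != n:
            raise ValueError("marks must align with positions")

    def __len__(self) -> int:
        return self.positions.shape[0]

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def dim(self) -> int:
        return self.positions.shape[1]

    def subset(self, keep: np.ndarray) -> "SpotSet":
        return SpotSet(
            self.positions[keep],
            self.intensities[keep],
            self.sizes[keep],
            self.channel_id,
        )


@dataclass
class CellMask:
    """Binary occupancy grid defining the analysis window Omega.

    ``measure`` is |Omega| = occupied pixels x pixel measure (nm^2 in 2D,
    nm^3 in 3D), exact by construction.  The mask supplies point-membership
    tests, uniform sampling for the null model, and boundary geometry for
    edge correction.
    """

    grid: np.ndarray
    pixel_size: tuple[float, ...]

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid).astype(bool)
        if self.grid.ndim not in (2, 3):
            raise ValueError("mask grid must be 2D or 3D")
        if self.grid.size == 0:
            raise ValueError("mask grid is empty")
        self.pixel_size = tuple(float(p) for p in np.atleast_1d(self.pixel_size))
        if len(self.pixel_size) == 1:
            self.pixel_size = self.pixel_size * self.grid.ndim
        if len(self.pixel_size) != self.grid.ndim:
            raise ValueError("pixel_size must have one entry per axis")
        if any(p <= 0 for p in self.pixel_size):
            raise ValueError("pixel_size must be positive")
        if self.measure <= 0:
            raise ValueError("mask measure must be positive (mask is empty)")
        self._fg_pixels: np.ndarray | None = None

    @property
    def dim(self) -> int:
        return self.grid.ndim

    @property
    def pixel_measure(self) -> float:
        return float(np.prod(self.pixel_size))

    @property
    def measure(self) -> float:
        return float(np.count_nonzero(self.grid)) * self.pixel_measure

    @property
    def extent(self) -> np.ndarray:
        """Physical grid extent (nm) per axis."""
        return np.asarray(self.grid.shape) * np.asarray(self.pixel_size)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean membership of physical points (nm); outside the grid is False."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        idx = np.floor(pts / np.asarray(self.pixel_size)).astype(np.int64)
        shape = np.asarray(self.grid.shape)
        inside = np.all((idx >= 0) & (idx < shape), axis=1)
        out = np.zeros(len(pts), dtype=bool)
        if inside.any():
            sel = idx[inside]
            out[inside] = self.grid[tuple(sel.T)]
        return out

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` points uniformly inside the mask (uniform foreground
        pixel + uniform jitter within the pixel)."""
        if self._fg_pixels is None:
            self._fg_pixels = np.argwhere(self.grid)
        base = self._fg_pixels[rng.integers(0, len(self._fg_pixels), size=n)]
        jitter = rng.random((n, self.dim))
        return (base + jitter) * np.asarray(self.pixel_size)


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

RESULT_COLUMNS = [
    "image",
    "pair",
    "N1",
    "N2",
    "n_coupled",
    "coupling_fraction_ch1",
    "coupling_fraction_ch2",
    "mean_coupling_distance_nm",
    "sd_coupling_distance_nm",
    "p_value",
    "alpha",
    "n_rings",
    "n_significant_rings",
    "status",
]

RING_COLUMNS = [
    "ring",
    "r_inner_nm",
    "r_outer_nm",
    "n_pairs",
    "K_hat",
    "ring_measure",
    "sigma",
    "z",
    "p_ring",
]


@dataclass
class ResultsTable:
    """One association analysis: a summary row plus per-ring diagnostics."""

    image: str
    pair: str
    N1: int
    N2: int
    n_coupled: float
    coupling_fraction_ch1: float
    coupling_fraction_ch2: float
    mean_coupling_distance_nm: float
    sd_coupling_distance_nm: float
    p_value: float
    alpha: float
    n_rings: int
    n_significant_rings: int
    status: str = "ok"
    rings: pd.DataFrame | None = None

    def row(self) -> pd.DataFrame:
        data = {c: [getattr(self, c)] for c in RESULT_COLUMNS}
        return pd.DataFrame(data, columns=RESULT_COLUMNS)


def write_results(tables: Sequence[ResultsTable], out_dir: str | os.PathLike) -> list[Path]:
    """Write one CSV per analysed image plus a concatenated ``batch.csv``.

    The batch file is always written (header-only for an empty input) and
    round-trips losslessly through :func:`pandas.read_csv`.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - depends on filesystem
        raise OSError(f"output directory not writable: {out}") from exc
    written: list[Path] = []
    rows = []
    for t in tables:
        row = t.row()
        rows.append(row)
        stem = Path(t.image).stem or "result"
        path = out / f"{stem}_results.csv"
        row.to_csv(path, index=False)
        written.append(path)
        if t.rings is not None:
            rpath = out / f"{stem}_rings.csv"
            t.rings.to_csv(rpath, index=False)
            written.append(rpath)
    batch = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=RESULT_COLUMNS)
    )
    bpath = out / "batch.csv"
    batch.to_csv(bpath, index=False)
    written.append(bpath)
    return written


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_image(
    path: str | os.PathLike,
    channel_map: Mapping[str, int] | None = None,
    pixel_size: float | Sequence[float] = 100.0,
    channel_axis: int | None = None,
) -> ImageStack:
    """Read a multichannel TIFF into an :class:`ImageStack`.

    The channel axis is taken to be the shortest axis unless ``channel_axis``
    is given.  ``channel_map`` assigns roles to channel indices, e.g.
    ``{"ch1": 0, "ch2": 1, "mask": 2}``; channels are reordered to
    ``(ch1, ch2[, mask])`` and named by role.  ``pixel_size`` (nm) comes from
    the caller/config since plain TIFF fixtures carry no calibrated metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = np.asarray(tifffile.imread(path))
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError("non-numeric pixel data")
    if arr.ndim == 2:
        arr = arr[None]
    if channel_axis is None:
        channel_axis = int(np.argmin(arr.shape))
    arr = np.moveaxis(arr, channel_axis, 0)
    names = [f"ch{i}" for i in range(arr.shape[0])]
    if channel_map is not None:
        order = [r for r in ("ch1", "ch2", "mask") if r in channel_map]
        idx = [int(channel_map[r]) for r in order]
        for i in idx:
            if not 0 <= i < arr.shape[0]:
                raise IndexError(
                    f"channel index {i} out of range for {arr.shape[0]}-channel image"
                )
        arr = arr[idx]
        names = list(order)
    return ImageStack(arr.astype(float), pixel_size=pixel_size, channel_names=names)


def read_mask_tiff(path: str | os.PathLike, pixel_size: float | Sequence[float]) -> CellMask:
    """Read a precomputed binary mask TIFF (any nonzero voxel is foreground)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    grid = np.asarray(tifffile.imread(path)) > 0
    if grid.ndim not in (2, 3):
        raise ValueError(f"mask TIFF must be 2D or 3D, got {grid.ndim}D")
    return CellMask(grid, pixel_size=pixel_size)


_DEFAULT_COLUMN_ALIASES = {
    "x": ("x [nm]", "x_nm", "x"),
    "y": ("y [nm]", "y_nm", "y"),
    "z": ("z [nm]", "z_nm", "z"),
    "channel": ("channel", "ch", "color"),
}


def _resolve_column(df: pd.DataFrame, role: str, column_map: Mapping[str, str] | None) -> str | None:
    if column_map and role in column_map:
        name = column_map[role]
        if name not in df.columns:
            raise KeyError(f"column {name!r} (role {role!r}) not in table")
        return name
    for cand in _DEFAULT_COLUMN_ALIASES[role]:
        if cand in df.columns:
            return cand
    return None


def read_localizations(
    path: str | os.PathLike,
    column_map: Mapping[str, str] | None = None,
    units: str = "nm",
    pixel_size: float = 1.0,
) -> dict[str, SpotSet]:
    """Read an SMLM localization CSV into one :class:`SpotSet` per channel.

    Coordinates are nm (``units='px'`` converts with ``pixel_size``); rows
    with non-finite coordinates are dropped and counted in the log.  Marks
    default to intensity 1 and size 1 per localization.  Position columns
    are stored in grid order (y, x[, z] -> (z,) y, x).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    xcol = _resolve_column(df, "x", column_map)
    ycol = _resolve_column(df, "y", column_map)
    if xcol is None or ycol is None:
        raise KeyError("localization table needs x and y columns")
    zcol = _resolve_column(df, "z", column_map)
    chcol = _resolve_column(df, "channel", column_map)

    cols = ([zcol] if zcol else []) + [ycol, xcol]
    coords = df[cols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    finite = np.all(np.isfinite(coords), axis=1)
    n_dropped = int((~finite).sum())
    if n_dropped:
        logger.warning("dropped %d localization rows with non-finite coordinates", n_dropped)
    coords = coords[finite]
    if units == "px":
        coords = coords * float(pixel_size)
    elif units != "nm":
        raise ValueError("units must be 'nm' or 'px'")

    if chcol is None:
        return {"1": SpotSet(coords, channel_id="1")}
    channels = df.loc[finite, chcol].astype(str).to_numpy()
    out: dict[str, SpotSet] = {}
    for ch in pd.unique(channels):
        sel = channels == ch
        out[str(ch)] = SpotSet(coords[sel], channel_id=str(ch))
    return out


# ---------------------------------------------------------------------------
# Molecular association map
# ---------------------------------------------------------------------------

#: The five documented map colors (plus black background).  Per the
#: association color code: isolated ch1 ("green") spots stay green, ch1 spots
#: associated with ch2 turn cyan; isolated ch2 ("red") spots stay red, ch2
#: spots associated with ch1 turn pink; the cell mask is deep blue.
MAP_COLORS = {
    "background": (0, 0, 0),
    "mask": (0, 0, 160),
    "ch1_isolated": (0, 255, 0),
    "ch1_associated": (0, 255, 255),
    "ch2_isolated": (255, 0, 0),
    "ch2_associated": (255, 105, 180),
}


def _paint_spots(
    canvas: np.ndarray,
    positions: np.ndarray,
    flags: np.ndarray,
    pixel_size: Sequence[float],
    color_on: tuple[int, int, int],
    color_off: tuple[int, int, int],
    radius_px: int,
) -> None:
    h, w = canvas.shape[:2]
    py, px = pixel_size[-2], pixel_size[-1]
    offsets = [
        (dy, dx)
        for dy in range(-radius_px, radius_px + 1)
        for dx in range(-radius_px, radius_px + 1)
        if dy * dy + dx * dx <= radius_px * radius_px
    ]
    for pos, flag in zip(positions, flags):
        cy = int(np.floor(pos[-2] / py))
        cx = int(np.floor(pos[-1] / px))
        color = color_on if flag else color_off
        for dy, dx in offsets:
            y, x = cy + dy, cx + dx
            if 0 <= y < h and 0 <= x < w:
                canvas[y, x] = color


def render_molecular_map(
    spots1: SpotSet,
    spots2: SpotSet,
    coupling,
    mask: CellMask,
    spot_radius_px: int = 2,
) -> np.ndarray:
    """Render the color-coded molecular association map as an RGB array.

    The cell mask is painted deep blue; each spot is painted per the
    four-color association code using its per-spot association flag
    (``P_i > 0.5``).  3D inputs are projected along z.  Deterministic given
    its inputs: ch1 spots are painted first, ch2 on top, each in index order.
    """
    if spots1.n and spots1.dim != mask.dim:
        raise ValueError("dimension mismatch between mask and spots")
    if spots2.n and spots2.dim != mask.dim:
        raise ValueError("dimension mismatch between mask and spots")
    grid = mask.grid if mask.dim == 2 else mask.grid.any(axis=0)
    canvas = np.zeros(grid.shape + (3,), dtype=np.uint8)
    canvas[grid] = MAP_COLORS["mask"]
    _paint_spots(
        canvas, spots1.positions, np.asarray(coupling.associated_ch1, dtype=bool),
        mask.pixel_size, MAP_COLORS["ch1_associated"], MAP_COLORS["ch1_isolated"],
        spot_radius_px,
    )
    _paint_spots(
        canvas, spots2.positions, np.asarray(coupling.associated_ch2, dtype=bool),
        mask.pixel_size, MAP_COLORS["ch2_associated"], MAP_COLORS["ch2_isolated"],
        spot_radius_px,
    )
    return canvas


def save_png(canvas: np.ndarray, path: str | os.PathLike) -> None:
    iio.imwrite(Path(path), canvas, extension=".png")
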