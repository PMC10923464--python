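"""End-to-end pipeline: detect -> segment -> couple -> export.

``run_single`` processes one input (TIFF image or localization CSV) into a
summary results row, a per-ring diagnostics CSV and a color-coded
molecular association map; ``run_batch`` maps it over a directory,
aggregating rows into one batch table where individual failures are logged
and flagged rather than aborting the run.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .coupling import EdgeWeights, filter_spots_to_mask, run_soda
from .detection import detect_spots
from .io import (
    RESULT_COLUMNS,
    CellMask,
    ResultsTable,
    SpotSet,
    read_image,
    read_localizations,
    read_mask_tiff,
    render_molecular_map,
    save_png,
    write_results,
)
from .masking import hierarchical_segment_cell_mask

logger = logging.getLogger(__name__)

__all__ = ["run_single", "run_batch"]


def _ring_table(profile, result) -> pd.DataFrame:
    radii = profile.rings.radii
    n_pairs = np.bincount(profile.pair_ring, minlength=profile.rings.n_rings)
    return pd.DataFrame(
        {
            "ring": np.arange(1, profile.rings.n_rings + 1),
            "r_inner_nm": radii[:-1],
            "r_outer_nm": radii[1:],
            "n_pairs": n_pairs,
            "K_hat": profile.k_hat,
            "ring_measure": profile.ring_measure,
            "sigma": result.sigma,
            "z": result.z,
            "p_ring": result.p_ring,
        }
    )


def _load_image_inputs(cfg: RunConfig, path: Path):
    channel_map = {"ch1": cfg.ch1, "ch2": cfg.ch2}
    if cfg.mask_channel is not None and not cfg.mask_file:
        channel_map["mask"] = cfg.mask_channel
    stack = read_image(path, channel_map=channel_map, pixel_size=cfg.pixel_size_nm)
    if cfg.mask_file:
        mask = read_mask_tiff(cfg.mask_file, pixel_size=cfg.pixel_size_nm)
    else:
        mask = hierarchical_segment_cell_mask(
            stack.channel("mask"), cfg.segmentation_params(), pixel_size=stack.pixel_size
        )
    params = cfg.detection_params()
    spots1 = detect_spots(stack.channel("ch1"), params, stack.pixel_size, mask, "1")
    spots2 = detect_spots(stack.channel("ch2"), params, stack.pixel_size, mask, "2")
    logger.info(
        "%s: detected %d ch1 and %d ch2 spots inside the mask", path.name, spots1.n, spots2.n
    )
    return spots1, spots2, mask


def _load_localization_inputs(cfg: RunConfig, path: Path):
    mask = read_mask_tiff(cfg.mask_file, pixel_size=cfg.pixel_size_nm)
    sets = read_localizations(
        path, column_map=cfg.column_map, units=cfg.loc_units, pixel_size=cfg.pixel_size_nm
    )
    def pick(key) -> SpotSet:
        k = str(key)
        if k not in sets:
            raise KeyError(f"channel {k!r} not present in {sorted(sets)}")
        return sets[k]
    spots1 = pick(cfg.ch1 if cfg.ch1 != 0 else "1")
    spots2 = pick(cfg.ch2 if cfg.ch2 != 1 else "2")
    n_before = (spots1.n, spots2.n)
    spots1 = filter_spots_to_mask(spots1, mask)
    spots2 = filter_spots_to_mask(spots2, mask)
    logger.info(
        "%s: kept %d/%d ch1 and %d/%d ch2 localizations inside the mask",
        path.name, spots1.n, n_before[0], spots2.n, n_before[1],
    )
    return spots1, spots2, mask


def _analyse(
    cfg: RunConfig,
    name: str,
    spots1: SpotSet,
    spots2: SpotSet,
    mask: CellMask,
    pair: str,
    weights: EdgeWeights,
):
    rings = cfg.ring_spec()
    profile, result = run_soda(
        spots1, spots2, mask,
        rings=rings, alpha=cfg.alpha, n_resamples=cfg.resamples, seed=cfg.seed,
        weights=weights,
    )
    return ResultsTable(
        image=name,
        pair=pair,
        N1=spots1.n,
        N2=spots2.n,
        n_coupled=result.n_coupled,
        coupling_fraction_ch1=result.coupling_fraction_ch1,
        coupling_fraction_ch2=result.coupling_fraction_ch2,
        mean_coupling_distance_nm=result.mean_distance,
        sd_coupling_distance_nm=result.sd_distance,
        p_value=result.p_value,
        alpha=cfg.alpha,
        n_rings=rings.n_rings,
        n_significant_rings=int(result.significant.sum()),
        rings=_ring_table(profile, result),
    ), result


def run_single(cfg: RunConfig, input_path: str | Path, out_dir: str | Path | None = None):
    """Analyse one input; write results CSVs and the molecular map PNG.

    Returns the list of :class:`ResultsTable` rows (two when ``cfg.both``
    requests the transposed channel-2 -> channel-1 run as well).
    """
    cfg.validate()
    path = Path(input_path)
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.mode == "image":
        spots1, spots2, mask = _load_image_inputs(cfg, path)
    else:
        spots1, spots2, mask = _load_localization_inputs(cfg, path)
    if spots1.n == 0 or spots2.n == 0:
        raise ValueError(f"{path.name}: no spots found in one of the channels")

    weights = EdgeWeights(mask)
    tables = []
    table, result = _analyse(cfg, path.name, spots1, spots2, mask, "ch1-ch2", weights)
    tables.append(table)
    if cfg.both:
        t2, _ = _analyse(cfg, path.name, spots2, spots1, mask, "ch2-ch1", weights)
        tables.append(t2)

    write_results(tables, out)
    canvas = render_molecular_map(spots1, spots2, result, mask)
    save_png(canvas, out / f"{path.stem}_map.png")
    logger.info(
        "%s: n_coupled=%.2f fraction_ch2=%.3f p=%.4g",
        path.name, result.n_coupled, result.coupling_fraction_ch2, result.p_value,
    )
    return tables


def run_batch(
    cfg: RunConfig,
    input_dir: str | Path,
    pattern: str | None = None,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Analyse every input matching ``pattern`` under ``input_dir``.

    Per-input failures are logged and recorded as a flagged row in the
    aggregate ``batch.csv`` instead of aborting the batch.  Raises when the
    pattern matches nothing.
    """
    cfg.validate()
    indir = Path(input_dir)
    if pattern is None:
        pattern = "*.tif*" if cfg.mode == "image" else "*_locs.csv"
    inputs = sorted(p for p in indir.glob(pattern) if p.is_file())
    if not inputs:
        raise FileNotFoundError(f"no inputs matching {pattern!r} in {indir}")
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    for path in inputs:
        try:
            tables = run_single(cfg, path, out_dir=out)
            rows.extend(t.row() for t in tables)
        except Exception as exc:  # noqa: BLE001 - batch isolates failures
            logger.error("%s failed: %s", path.name, exc)
            failed = {c: [np.nan] for c in RESULT_COLUMNS}
            failed["image"] = [path.name]
            failed["pair"] = ["ch1-ch2"]
            failed["status"] = [f"error: {exc}"]
            rows.append(pd.DataFrame(failed, columns=RESULT_COLUMNS))
    aggregate = pd.concat(rows, ignore_index=True)
    aggregate.to_csv(out / "batch.csv", index=False)
    return aggregate
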