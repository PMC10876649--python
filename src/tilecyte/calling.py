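"""Per-tile marker aggregation, cell-type calling and composition tables.

A tile's phenotype is the marker channel with the highest aggregated
normalized intensity over the tile's pixels (argmax typing).  The nuclear
channel is excluded from the call — it marks all cells.  Aggregation defaults
to the per-tile mean, which is robust to single hot pixels; median and max
are selectable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .datatypes import UNASSIGNED, ChannelImage, TileLabelImage
from .errors import NotNormalizedError, TilecyteError

_AGGREGATORS = {
    "mean": ndimage.mean,
    "median": ndimage.median,
    "max": ndimage.maximum,
}


def tile_intensity_matrix(
    tiles: TileLabelImage,
    channels: list[ChannelImage],
    statistic: str = "mean",
) -> pd.DataFrame:
    """Aggregate each normalized channel over each tile's pixels.

    Returns a DataFrame indexed by ``tile_id`` (1..n_tiles) with one column
    per channel; entry (t, c) is ``statistic`` over channel c's values on
    tile t.
    """
    if statistic not in _AGGREGATORS:
        raise ValueError(f"statistic must be one of {sorted(_AGGREGATORS)}")
    if not channels:
        raise TilecyteError("need at least one marker channel")
    bad = [ch.name for ch in channels if not ch.normalized]
    if bad:
        raise NotNormalizedError(f"channels must be normalized: {bad}")
    for ch in channels:
        if ch.shape != tiles.shape:
            raise ValueError(f"channel '{ch.name}' shape differs from tile image")
    assert (tiles.tile_areas() > 0).all(), "every tile must own at least one pixel"

    agg = _AGGREGATORS[statistic]
    index = np.arange(1, tiles.n_tiles + 1)
    data = {
        ch.name: np.asarray(agg(ch.values, labels=tiles.labels, index=index))
        for ch in channels
    }
    out = pd.DataFrame(data, index=pd.Index(index, name="tile_id"))
    return out


def call_tile_types(
    matrix: pd.DataFrame,
    min_score: float = 0.0,
    tie_order: list[str] | None = None,
    regions: pd.Series | None = None,
) -> pd.DataFrame:
    """Call one type per tile by highest aggregated normalized intensity.

    Exact ties go to the earliest channel in ``tie_order`` (default: the
    matrix column order).  Tiles whose winning score falls below
    ``min_score`` are called ``unassigned``; the default 0 assigns every
    tile, the exhaustive three-way regime.  ``regions`` (tile_id -> region
    name) is carried through when given.
    """
    if tie_order is None:
        tie_order = list(matrix.columns)
    if sorted(tie_order) != sorted(matrix.columns):
        raise ValueError("tie_order must be a permutation of the matrix columns")
    ordered = matrix[tie_order]
    values = ordered.to_numpy(dtype=float)
    win = np.argmax(values, axis=1)  # first max -> earliest in tie_order
    score = values[np.arange(len(values)), win]
    called = np.array(tie_order, dtype=object)[win]
    called[score < min_score] = UNASSIGNED
    out = pd.DataFrame(
        {
            "tile_id": matrix.index.to_numpy(),
            "called_type": called,
            "winning_score": score,
        }
    )
    if regions is not None:
        out["region"] = out["tile_id"].map(regions).to_numpy()
    return out


def composition_table(
    types: pd.DataFrame,
    sample_id: str,
    type_names: list[str] | None = None,
) -> pd.DataFrame:
    """Tile counts and proportions per region stratum and combined.

    Strata are ``lining``, ``sub-lining`` and ``combined``; strata with no
    tiles are omitted.  Proportions are percentages of the stratum's tile
    total, so each stratum sums to 100.  ``type_names`` fixes the category
    universe (plus ``unassigned``) so zero-count rows appear consistently
    across samples.
    """
    if types.empty:
        raise TilecyteError("no tiles: cannot tabulate an empty type table")
    if type_names is None:
        type_names = sorted(set(types["called_type"]) - {UNASSIGNED})
    categories = list(type_names) + [UNASSIGNED]

    frames = []
    strata: list[tuple[str, pd.DataFrame]] = [("combined", types)]
    if "region" in types.columns:
        strata = [
            (region, grp) for region, grp in types.groupby("region", sort=True)
        ] + strata
    for stratum, grp in strata:
        total = len(grp)
        counts = grp["called_type"].value_counts()
        for t in categories:
            c = int(counts.get(t, 0))
            frames.append(
                {
                    "sample": sample_id,
                    "region": stratum,
                    "type": t,
                    "count": c,
                    "proportion_pct": 100.0 * c / total,
                    "n_tiles": total,
                }
            )
    return pd.DataFrame(frames)


__all__ = ["tile_intensity_matrix", "call_tile_types", "composition_table"]
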