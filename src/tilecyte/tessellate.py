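"""Discrete Voronoi tessellation of an ROI about nucleus centroids.

Every ROI pixel (at its pixel-centre coordinate) is assigned the id of the
Euclidean-nearest nucleus centroid, so each tile contains exactly one nucleus
and tile borders run equidistant between neighbouring nuclei.  The
tessellation is computed on the pixel grid rather than by polygon clipping:
this is exact for arbitrary ROI masks and treats tiles as what they are
downstream — sets of pixels.

Ties (a pixel exactly equidistant from several centroids) are broken by the
smallest nucleus id, so the labelling is bit-reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .datatypes import (
    REGION_NAMES,
    NucleusSet,
    RegionMask,
    TileLabelImage,
    containing_pixels,
)
from .errors import CentroidOutsideROIError, NoNucleiError

# Relative slack below which two centroid distances are treated as possibly
# tied and re-resolved by the exact brute-force rule.
_TIE_RTOL = 1e-9


def _nearest_by_scan(points: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Index of nearest centroid per point; ties -> lowest index (= lowest id)."""
    d2 = ((points[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)


def voronoi_label(nuclei: NucleusSet, region_mask: RegionMask) -> TileLabelImage:
    """Label every ROI pixel with the id of its nearest nucleus.

    Parameters
    ----------
    nuclei:
        Seed centroids; all must lie on ROI pixels.
    region_mask:
        Defines the ROI (nonzero pixels). Background pixels are labelled 0.

    Returns
    -------
    TileLabelImage
        ``n_tiles`` equals the number of nuclei; the set of nonzero labels is
        exactly the set of nucleus ids.
    """
    if len(nuclei) == 0:
        raise NoNucleiError("no nuclei: cannot tessellate an ROI without seeds")
    roi = region_mask.roi
    px = nuclei.pixels()
    if (
        (px[:, 0] < 0).any()
        or (px[:, 0] >= roi.shape[0]).any()
        or (px[:, 1] < 0).any()
        or (px[:, 1] >= roi.shape[1]).any()
        or not roi[px[:, 0], px[:, 1]].all()
    ):
        bad = [
            int(i)
            for i, (r, c) in zip(nuclei.ids, px)
            if not (0 <= r < roi.shape[0] and 0 <= c < roi.shape[1] and roi[r, c])
        ]
        raise CentroidOutsideROIError(f"centroid outside ROI for nucleus ids {bad}")

    rows, cols = np.nonzero(roi)
    points = np.column_stack([rows, cols]).astype(float)
    centroids = nuclei.centroids
    labels = np.zeros(roi.shape, dtype=np.int32)

    if len(nuclei) == 1:
        labels[rows, cols] = nuclei.ids[0]
        return TileLabelImage(labels, 1)

    # Fast path: KD-tree nearest neighbour.  Pixels whose two nearest
    # centroids are (nearly) equidistant are re-resolved by the exact
    # brute-force rule so the tie-break is always "smallest id".
    tree = cKDTree(centroids)
    dist, idx = tree.query(points, k=2)
    nearest = idx[:, 0].astype(np.intp)
    ambiguous = (dist[:, 1] - dist[:, 0]) <= _TIE_RTOL * (dist[:, 0] + 1.0)
    if ambiguous.any():
        nearest[ambiguous] = _nearest_by_scan(points[ambiguous], centroids)
    labels[rows, cols] = nuclei.ids[nearest]
    return TileLabelImage(labels, len(nuclei))


def assign_tile_regions(
    tiles: TileLabelImage,
    region_mask: RegionMask,
    nuclei: NucleusSet,
    rule: str = "nucleus_position",
) -> pd.DataFrame:
    """Assign each tile to a tissue region (lining / sub-lining).

    ``nucleus_position`` (default): a tile's region is the region label at the
    pixel containing its nucleus — a cell's identity is where its nucleus
    sits.  ``majority_pixel``: the region covering most of the tile's pixels,
    ties resolved by the nucleus-position region.

    Returns a table with one row per tile: ``tile_id``, ``region`` (name),
    ``area_px`` and ``nucleus_id``; areas sum to the ROI pixel count.
    """
    if rule not in ("nucleus_position", "majority_pixel"):
        raise ValueError(f"unknown region rule '{rule}'")
    if tiles.shape != region_mask.shape:
        raise ValueError("tile labels and region mask differ in shape")

    n = tiles.n_tiles
    areas = tiles.tile_areas()
    px = nuclei.pixels()
    nucleus_region = region_mask.labels[px[:, 0], px[:, 1]].astype(np.int64)

    if rule == "nucleus_position":
        region_code = nucleus_region
    else:
        # Joint histogram over (tile id, region code) for ROI pixels.
        t = tiles.labels.ravel()
        r = region_mask.labels.ravel().astype(np.int64)
        inside = t > 0
        counts = np.bincount(
            (t[inside] - 1) * 3 + r[inside], minlength=n * 3
        ).reshape(n, 3)
        lining, sublining = counts[:, 1], counts[:, 2]
        region_code = np.where(
            lining > sublining, 1, np.where(sublining > lining, 2, nucleus_region)
        )

    return pd.DataFrame(
        {
            "tile_id": nuclei.ids,
            "region": [REGION_NAMES[int(c)] for c in region_code],
            "area_px": areas,
            "nucleus_id": nuclei.ids,
        }
    )


__all__ = ["voronoi_label", "assign_tile_regions"]
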