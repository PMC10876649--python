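"""Nucleus detection from the DAPI channel.

A classical, fully deterministic pipeline seeds the tessellation: Gaussian
smoothing, foreground by Otsu (or a fixed threshold) over ROI pixels,
connected components filtered by area, watershed splitting of merged blobs
from local intensity maxima, then one intensity-weighted centroid per final
component.  Centroids are ordered lexicographically by (row, col) and ids
assigned 1..n, so identical inputs always yield the identical NucleusSet.

The detector targets blob-like nuclear stains; a pre-computed NucleusSet can
always be supplied downstream instead (CSV ``id,row,col``), decoupling the
tessellation from detection quality.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from .datatypes import ChannelImage, DetectionParams, NucleusSet, RegionMask
from .errors import EmptyROIError


def detect_nuclei(
    dapi: ChannelImage,
    roi_mask: RegionMask,
    params: DetectionParams = DetectionParams(),
) -> NucleusSet:
    """Detect nucleus centroids in a nuclear-stain channel.

    Returns an empty :class:`NucleusSet` when the DAPI signal is flat over
    the ROI (nothing to detect); raises :class:`EmptyROIError` when the ROI
    itself is empty.
    """
    roi = roi_mask.roi
    if dapi.shape != roi.shape:
        raise ValueError("DAPI channel and ROI mask differ in shape")
    if not roi.any():
        raise EmptyROIError("empty ROI: no pixels to detect nuclei in")

    img = dapi.values
    if params.smoothing_sd > 0:
        img = ndimage.gaussian_filter(img, params.smoothing_sd)

    roi_vals = img[roi]
    if roi_vals.max() == roi_vals.min():
        return NucleusSet.empty()
    if params.threshold_method == "otsu":
        thresh = threshold_otsu(roi_vals)
    else:
        thresh = float(params.fixed_threshold)

    fg = (img > thresh) & roi
    if not fg.any():
        return NucleusSet.empty()

    comp, n_comp = ndimage.label(fg)
    if params.min_blob_area > 1:
        areas = np.bincount(comp.ravel(), minlength=n_comp + 1)
        keep = areas >= params.min_blob_area
        keep[0] = False
        fg = keep[comp]
        comp, n_comp = ndimage.label(fg)
    if n_comp == 0:
        return NucleusSet.empty()

    # Split merged blobs: local maxima per component seed a watershed.
    peaks = peak_local_max(
        img,
        min_distance=params.min_distance,
        labels=comp,
        exclude_border=False,
    )
    if len(peaks) == 0:
        return NucleusSet.empty()
    markers = np.zeros(img.shape, dtype=np.int32)
    markers[peaks[:, 0], peaks[:, 1]] = np.arange(1, len(peaks) + 1)
    parts = watershed(-img, markers, mask=fg)

    index = np.arange(1, len(peaks) + 1)
    present = np.isin(index, np.unique(parts))
    index = index[present]
    if len(index) == 0:
        return NucleusSet.empty()
    centroids = np.array(ndimage.center_of_mass(img, labels=parts, index=index))

    # Keep centroids whose containing pixel is on the ROI.
    px = np.floor(centroids + 0.5).astype(int)
    ok = (
        (px[:, 0] >= 0)
        & (px[:, 0] < roi.shape[0])
        & (px[:, 1] >= 0)
        & (px[:, 1] < roi.shape[1])
    )
    ok &= roi[px[:, 0].clip(0, roi.shape[0] - 1), px[:, 1].clip(0, roi.shape[1] - 1)]
    centroids, px = centroids[ok], px[ok]
    if len(centroids) == 0:
        return NucleusSet.empty()

    # Rank-stable ordering, then deterministically drop any later centroid
    # that rounds onto an already-occupied pixel (rare tight splits).
    order = np.lexsort((centroids[:, 1], centroids[:, 0]))
    centroids, px = centroids[order], px[order]
    _, first = np.unique(px, axis=0, return_index=True)
    centroids = centroids[np.sort(first)]
    return NucleusSet(centroids)


def match_nuclei(
    detected: NucleusSet, truth: NucleusSet, max_dist: float = 3.0
) -> dict[str, float]:
    """Score detections against ground truth by greedy nearest pairing.

    Candidate (detected, true) pairs within ``max_dist`` pixels are accepted
    greedily in order of increasing distance, each point used at most once.
    Returns precision, recall, F1 and the number of matches.
    """
    n_det, n_true = len(detected), len(truth)
    if n_det == 0 or n_true == 0:
        return {"precision": 0.0, "recall": 0.0, "f1": 0.0, "n_matched": 0}
    d = np.linalg.norm(
        detected.centroids[:, None, :] - truth.centroids[None, :, :], axis=2
    )
    pairs = np.argwhere(d <= max_dist)
    order = np.argsort(d[pairs[:, 0], pairs[:, 1]], kind="stable")
    used_det: set[int] = set()
    used_true: set[int] = set()
    matched = 0
    for i, j in pairs[order]:
        if i in used_det or j in used_true:
            continue
        used_det.add(int(i))
        used_true.add(int(j))
        matched += 1
    precision = matched / n_det
    recall = matched / n_true
    f1 = 0.0 if matched == 0 else 2 * precision * recall / (precision + recall)
    return {"precision": precision, "recall": recall, "f1": f1, "n_matched": matched}


__all__ = ["detect_nuclei", "match_nuclei"]
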