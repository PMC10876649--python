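"""Channel-level preprocessing: despeckling and robust normalization.

Cross-channel comparison of staining intensity (the "highest normalized
signal" typing rule) is only meaningful once every marker channel is on a
common scale.  Channels are therefore rescaled by robust percentiles computed
over ROI pixels only, and optionally despeckled first with a small median
filter to suppress single-pixel outliers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import replace

import numpy as np
from scipy import ndimage

from .datatypes import ChannelImage, RegionMask
from .errors import EmptyROIError

logger = logging.getLogger(__name__)


class DegenerateChannelWarning(UserWarning):
    """A channel is constant over the ROI; normalization returns all zeros."""


def _median_footprint(radius: float) -> np.ndarray:
    """Inflated-disk footprint for a fractional-radius median filter.

    Includes offsets with dr**2 + dc**2 <= r**2 + 1 (r = max(radius, 0.5)),
    the common imaging convention under which radius 0.5 gives the 5-pixel
    cross (centre + 4-neighbours).
    """
    r = max(float(radius), 0.5)
    k = int(np.floor(np.sqrt(r * r + 1.0)))
    dr, dc = np.mgrid[-k : k + 1, -k : k + 1]
    return (dr * dr + dc * dc) <= r * r + 1.0


def median_despeckle(channel: ChannelImage, radius: float = 0.5) -> ChannelImage:
    """Median outlier filter over a disk-like neighbourhood.

    Each pixel is replaced by the median over nearby pixels (see
    :func:`_median_footprint`); borders are handled by edge reflection and
    the image dimensions are unchanged.  ``radius=0`` is the identity.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        return channel
    out = ndimage.median_filter(
        channel.values, footprint=_median_footprint(radius), mode="reflect"
    )
    return replace(channel, values=out)


def normalize_channel(
    channel: ChannelImage,
    roi_mask: RegionMask,
    p_low: float = 1.0,
    p_high: float = 99.0,
) -> ChannelImage:
    """Rescale a channel to [0, 1] by ROI percentiles.

    ``out = clip((x - q_low) / (q_high - q_low), 0, 1)`` with q_low/q_high
    the ``p_low``/``p_high`` linear-interpolation percentiles of the ROI
    pixel values.  Percentiles are computed over ROI pixels only so that
    background outside the tissue cannot shift the scale.

    A channel that is constant over the ROI has no dynamic range; it is
    returned as all zeros with a :class:`DegenerateChannelWarning`.
    """
    if not 0 <= p_low < p_high <= 100:
        raise ValueError("need 0 <= p_low < p_high <= 100")
    roi = roi_mask.roi
    if channel.shape != roi.shape:
        raise ValueError("channel and ROI mask differ in shape")
    if not roi.any():
        raise EmptyROIError("cannot normalize over an empty ROI")

    vals = channel.values[roi]
    q_low, q_high = np.percentile(vals, [p_low, p_high], method="linear")
    if q_high == q_low:
        warnings.warn(
            f"channel '{channel.name}' is constant over the ROI; "
            "normalized output is all zeros",
            DegenerateChannelWarning,
            stacklevel=2,
        )
        logger.warning("degenerate normalization for channel '%s'", channel.name)
        return ChannelImage(np.zeros_like(channel.values), channel.name, normalized=True)
    out = np.clip((channel.values - q_low) / (q_high - q_low), 0.0, 1.0)
    return ChannelImage(out, channel.name, normalized=True)


__all__ = ["median_despeckle", "normalize_channel", "DegenerateChannelWarning"]
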