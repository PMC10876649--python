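"""Core containers for tile-based quantification of multiplex tissue images.

The pipeline's vocabulary:

* :class:`MultiplexImage` — channel-stacked intensity raster (one DAPI/nuclear
  channel plus marker channels such as CD31, CD68, DKK3).
* :class:`RegionMask` — integer raster labelling background (0), capsule
  lining (1) and sub-lining (2); the ROI is the set of nonzero pixels.
* :class:`NucleusSet` — ordered nucleus centroids seeding the tessellation.
* :class:`TileLabelImage` — every ROI pixel assigned to exactly one Voronoi
  tile; tile id equals nucleus id.

Coordinates are (row, col) at pixel centres, 0-based, y-down.  Pixels are
assumed isotropic with side ``pixel_size`` µm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import TilecyteError

#: Region label codes used throughout.
BACKGROUND = 0
LINING = 1
SUBLINING = 2
REGION_NAMES = {LINING: "lining", SUBLINING: "sub-lining"}
REGION_CODES = {name: code for code, name in REGION_NAMES.items()}

#: Name of the tile-type category for tiles below the calling threshold.
UNASSIGNED = "unassigned"


def containing_pixels(centroids: np.ndarray) -> np.ndarray:
    """Integer (row, col) of the pixel containing each subpixel centroid.

    Pixel (i, j) spans [i-0.5, i+0.5) x [j-0.5, j+0.5) about its centre.
    """
    centroids = np.asarray(centroids, dtype=float)
    return np.floor(centroids + 0.5).astype(np.intp)


@dataclass(frozen=True)
class RegionMask:
    """Tissue-region raster: 0=background, 1=lining, 2=sub-lining."""

    labels: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise TilecyteError("region mask must be 2-D")
        extra = set(np.unique(labels)) - {BACKGROUND, LINING, SUBLINING}
        if extra:
            raise TilecyteError(f"region mask contains invalid labels {sorted(extra)}")
        if not self.pixel_size > 0:
            raise TilecyteError("pixel_size must be positive")
        object.__setattr__(self, "labels", labels.astype(np.int8, copy=False))

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def roi(self) -> np.ndarray:
        """Boolean mask of ROI (nonzero) pixels."""
        return self.labels > 0

    @property
    def roi_area_px(self) -> int:
        return int(np.count_nonzero(self.labels))

    def region_name_at(self, row: int, col: int) -> str:
        code = int(self.labels[row, col])
        if code == BACKGROUND:
            raise TilecyteError(f"pixel ({row}, {col}) is background")
        return REGION_NAMES[code]


@dataclass(frozen=True)
class NucleusSet:
    """Ordered nucleus centroids; ids are contiguous 1..n in list order."""

    centroids: np.ndarray  # (n, 2) float, (row, col)
    ids: np.ndarray = None  # (n,) int

    def __post_init__(self):
        centroids = np.asarray(self.centroids, dtype=float).reshape(-1, 2)
        n = len(centroids)
        ids = self.ids
        if ids is None:
            ids = np.arange(1, n + 1)
        ids = np.asarray(ids, dtype=np.int64)
        if not np.array_equal(ids, np.arange(1, n + 1)):
            raise TilecyteError("nucleus ids must be contiguous 1..n in list order")
        if n:
            px = containing_pixels(centroids)
            if len(np.unique(px, axis=0)) != n:
                raise TilecyteError("two nucleus centroids occupy the same pixel")
        object.__setattr__(self, "centroids", centroids)
        object.__setattr__(self, "ids", ids)

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def empty(cls) -> "NucleusSet":
        return cls(np.empty((0, 2), dtype=float))

    def pixels(self) -> np.ndarray:
        """(n, 2) integer pixel coordinates containing each centroid."""
        return containing_pixels(self.centroids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.ids, "row": self.centroids[:, 0], "col": self.centroids[:, 1]}
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "NucleusSet":
        df = df.sort_values("id")
        return cls(df[["row", "col"]].to_numpy(dtype=float), df["id"].to_numpy())


@dataclass(frozen=True)
class ChannelImage:
    """A single named channel; ``normalized`` marks values rescaled to [0, 1]."""

    values: np.ndarray
    name: str
    normalized: bool = False

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise TilecyteError(f"channel '{self.name}' must be 2-D")
        if self.normalized and (values.min() < -1e-12 or values.max() > 1 + 1e-12):
            raise TilecyteError(f"normalized channel '{self.name}' outside [0, 1]")
        object.__setattr__(self, "values", values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class MultiplexImage:
    """Channel-stacked 2-D intensity raster with named channels.

    Exactly one channel (``dapi_name``, default "DAPI") is the nuclear stain;
    the remaining channels are cell-type markers.
    """

    channels: np.ndarray  # (C, H, W) float
    channel_names: tuple[str, ...]
    pixel_size: float = 1.0
    dapi_name: str = "DAPI"

    def __post_init__(self):
        channels = np.asarray(self.channels, dtype=float)
        names = tuple(self.channel_names)
        if channels.ndim != 3 or channels.shape[0] != len(names):
            raise TilecyteError("channels must be (C, H, W) matching channel_names")
        if len(set(names)) != len(names):
            raise TilecyteError("channel names must be unique")
        if self.dapi_name not in names:
            raise TilecyteError(f"missing nuclear channel '{self.dapi_name}'")
        if not self.pixel_size > 0:
            raise TilecyteError("pixel_size must be positive")
        object.__setattr__(self, "channels", channels)
        object.__setattr__(self, "channel_names", names)

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels.shape[1:]

    @property
    def marker_names(self) -> tuple[str, ...]:
        return tuple(n for n in self.channel_names if n != self.dapi_name)

    def channel(self, name: str) -> ChannelImage:
        idx = self.channel_names.index(name)
        return ChannelImage(self.channels[idx], name)

    @property
    def dapi(self) -> ChannelImage:
        return self.channel(self.dapi_name)


@dataclass(frozen=True)
class TileLabelImage:
    """Discrete Voronoi tessellation: tile id per ROI pixel, 0 outside ROI."""

    labels: np.ndarray  # (H, W) int32
    n_tiles: int

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise TilecyteError("tile label image must be 2-D")
        object.__setattr__(self, "labels", labels.astype(np.int32, copy=False))

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def tile_areas(self) -> np.ndarray:
        """Pixel count per tile, indexed 1..n_tiles."""
        return np.bincount(self.labels.ravel(), minlength=self.n_tiles + 1)[1:]


@dataclass(frozen=True)
class DetectionParams:
    """Parameters of the classical smooth -> threshold -> watershed detector."""

    smoothing_sd: float = 1.0
    threshold_method: str = "otsu"  # "otsu" | "fixed"
    fixed_threshold: float | None = None
    min_distance: int = 3
    min_blob_area: int = 5

    def __post_init__(self):
        if self.smoothing_sd < 0:
            raise TilecyteError("smoothing_sd must be >= 0")
        if self.threshold_method not in ("otsu", "fixed"):
            raise TilecyteError("threshold_method must be 'otsu' or 'fixed'")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise TilecyteError("fixed threshold_method requires fixed_threshold")
        if self.min_distance < 1:
            raise TilecyteError("min_distance must be >= 1")
        if self.min_blob_area < 1:
            raise TilecyteError("min_blob_area must be >= 1")


__all__ = [
    "BACKGROUND",
    "LINING",
    "SUBLINING",
    "REGION_NAMES",
    "REGION_CODES",
    "UNASSIGNED",
    "containing_pixels",
    "RegionMask",
    "NucleusSet",
    "ChannelImage",
    "MultiplexImage",
    "TileLabelImage",
    "DetectionParams",
    "replace",
]
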