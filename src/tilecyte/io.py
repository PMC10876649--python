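"""Reading and writing the pipeline's file formats.

Multi-channel images are multi-page TIFFs with the channel name in each
page's ImageDescription tag; a sidecar YAML (``<stem>.meta.yaml``) carries
pixel size and, as a fallback, the channel-index -> name mapping.  Region
masks are single-channel TIFF or PNG; tables are CSV; configs are YAML.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .datatypes import MultiplexImage, NucleusSet, RegionMask, TileLabelImage
from .errors import TilecyteError


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.yaml")


def write_multiplex_tiff(image: MultiplexImage, path) -> None:
    path = Path(path)
    with tifffile.TiffWriter(path) as tw:
        for name, plane in zip(image.channel_names, image.channels):
            tw.write(plane.astype(np.float32), description=name, contiguous=False)
    with open(_sidecar(path), "w") as fh:
        yaml.safe_dump(
            {
                "pixel_size_um": float(image.pixel_size),
                "channels": list(image.channel_names),
                "dapi": image.dapi_name,
            },
            fh,
        )


def read_multiplex_tiff(path, channels_yaml=None) -> MultiplexImage:
    """Read a multi-page TIFF; channel names from page descriptions or YAML."""
    path = Path(path)
    meta: dict = {}
    meta_path = Path(channels_yaml) if channels_yaml else _sidecar(path)
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = yaml.safe_load(fh) or {}
    with tifffile.TiffFile(path) as tf:
        planes = [p.asarray() for p in tf.pages]
        names = [p.description or "" for p in tf.pages]
    if meta.get("channels"):
        names = list(meta["channels"])
    if len(names) != len(planes) or any(not n for n in names):
        raise TilecyteError(
            f"cannot determine channel names for '{path}'; provide a sidecar YAML"
        )
    return MultiplexImage(
        np.stack([np.asarray(p, dtype=float) for p in planes]),
        tuple(names),
        pixel_size=float(meta.get("pixel_size_um", 1.0)),
        dapi_name=meta.get("dapi", "DAPI"),
    )


def write_region_mask(mask: RegionMask, path) -> None:
    path = Path(path)
    data = mask.labels.astype(np.uint8)
    if path.suffix.lower() == ".png":
        iio.imwrite(path, data)
    else:
        tifffile.imwrite(path, data)
    with open(_sidecar(path), "w") as fh:
        yaml.safe_dump({"pixel_size_um": float(mask.pixel_size)}, fh)


def read_region_mask(path, pixel_size: float | None = None) -> RegionMask:
    path = Path(path)
    if not path.exists():
        raise TilecyteError(f"region mask not found: {path}")
    if path.suffix.lower() == ".png":
        data = np.asarray(iio.imread(path))
    else:
        data = tifffile.imread(path)
    if pixel_size is None:
        meta_path = _sidecar(path)
        if meta_path.exists():
            with open(meta_path) as fh:
                pixel_size = float((yaml.safe_load(fh) or {}).get("pixel_size_um", 1.0))
        else:
            pixel_size = 1.0
    return RegionMask(np.asarray(data, dtype=np.int8), pixel_size=pixel_size)


def write_nuclei_csv(nuclei: NucleusSet, path) -> None:
    nuclei.to_dataframe().to_csv(path, index=False, float_format="%.10g")


def read_nuclei_csv(path) -> NucleusSet:
    path = Path(path)
    if not path.exists():
        raise TilecyteError(f"nuclei table not found: {path}")
    return NucleusSet.from_dataframe(pd.read_csv(path))


def write_tile_labels(tiles: TileLabelImage, path) -> None:
    dtype = np.uint16 if tiles.n_tiles < 2**16 else np.uint32
    tifffile.imwrite(Path(path), tiles.labels.astype(dtype))


def read_tile_labels(path) -> TileLabelImage:
    data = tifffile.imread(Path(path))
    return TileLabelImage(np.asarray(data, dtype=np.int32), int(data.max()))


def read_yaml(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise TilecyteError(f"config file not found: {path}")
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_yaml(obj: dict, path) -> None:
    with open(Path(path), "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def write_csv_with_header(df: pd.DataFrame, path, comment: str | None = None) -> None:
    """Write a CSV, optionally preceded by a single ``#`` comment line."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(Path(path), comment="#")


__all__ = [
    "write_multiplex_tiff",
    "read_multiplex_tiff",
    "write_region_mask",
    "read_region_mask",
    "write_nuclei_csv",
    "read_nuclei_csv",
    "write_tile_labels",
    "read_tile_labels",
    "read_yaml",
    "write_yaml",
    "write_csv_with_header",
    "read_csv",
]
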