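"""Synthetic multiplex tissue images with known per-nucleus cell types.

The generator emulates the structure of multiplexed immunofluorescence ROIs
of joint-capsule tissue: a thin lining band along one edge over a deeper
sub-lining region, on the order of a thousand nuclei per ROI, three marker
classes (DKK3+ fibroblasts, CD68+ macrophages, CD31+ endothelium) with
macrophages enriched in the lining and endothelium in the sub-lining, and
marker signal concentrated within each cell's Voronoi tile on top of an
autofluorescence-like background with Gaussian noise.

Every sample carries a ground-truth table (nucleus position, region, true
type), so the whole downstream pipeline — detection, tessellation, typing,
composition, group statistics — is testable end to end without external
image data.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import (
    LINING,
    REGION_NAMES,
    SUBLINING,
    MultiplexImage,
    NucleusSet,
    RegionMask,
)
from .errors import PlacementInfeasibleError, TilecyteError, UnknownCellTypeError
from .tessellate import voronoi_label

#: Overall tile compositions the two study groups are calibrated to
#: (fractions of DKK3+/CD68+/CD31+ tiles).
COMPARATOR_COMPOSITION = {"DKK3": 0.670, "CD68": 0.191, "CD31": 0.139}
FROZEN_SHOULDER_COMPOSITION = {"DKK3": 0.503, "CD68": 0.271, "CD31": 0.226}

#: Lining-band compositions expressing CD68 lining enrichment and CD31
#: sub-lining enrichment; the sub-lining composition is solved from the
#: overall target by area weighting.
_COMPARATOR_LINING = {"DKK3": 0.55, "CD68": 0.35, "CD31": 0.10}
_FROZEN_LINING = {"DKK3": 0.38, "CD68": 0.45, "CD31": 0.17}

# Attempt cap for hard-core rejection sampling, per requested nucleus.
_MAX_ATTEMPTS_PER_NUCLEUS = 10_000


@dataclass
class SimulationConfig:
    """All knobs of one simulated sample.

    The lining is a band of ``lining_depth`` pixels along the top edge; the
    rest of the image is sub-lining (the whole frame is ROI).  Intensities
    are arbitrary linear units.  ``signal_mean[t][c]`` is the marker-channel
    mean added over the Voronoi tile of a type-``t`` cell.
    """

    image_height: int = 512
    image_width: int = 512
    pixel_size: float = 0.5  # µm/px
    lining_depth: int = 64
    n_nuclei: int = 1000
    min_spacing: float = 8.0
    nucleus_radius: float = 3.0
    channel_names: tuple[str, ...] = ("DAPI", "CD31", "CD68", "DKK3")
    composition_by_region: dict[str, dict[str, float]] = field(default_factory=dict)
    signal_mean: dict[str, dict[str, float]] = field(default_factory=dict)
    background_level: dict[str, float] = field(default_factory=dict)
    noise_sd: dict[str, float] = field(default_factory=dict)
    dapi_peak: float = 200.0
    seed: int | None = None

    def __post_init__(self):
        self.channel_names = tuple(self.channel_names)
        if not self.composition_by_region:
            self.composition_by_region = region_compositions(
                COMPARATOR_COMPOSITION, _COMPARATOR_LINING, self.lining_fraction
            )
        if not self.signal_mean:
            self.signal_mean = {
                t: {c: (60.0 if c == t else 0.0) for c in self.marker_names}
                for t in self.cell_types
            }
        if not self.background_level:
            self.background_level = {"DAPI": 0.0, **{c: 10.0 for c in self.marker_names}}
        if not self.noise_sd:
            self.noise_sd = {"DAPI": 5.0, **{c: 10.0 for c in self.marker_names}}
        self.validate()

    @property
    def marker_names(self) -> tuple[str, ...]:
        return tuple(c for c in self.channel_names if c != "DAPI")

    @property
    def cell_types(self) -> tuple[str, ...]:
        first = next(iter(self.composition_by_region.values()), None)
        if first is None:
            return self.marker_names
        return tuple(first)

    @property
    def lining_fraction(self) -> float:
        return self.lining_depth / self.image_height

    def validate(self) -> None:
        for region, probs in self.composition_by_region.items():
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise TilecyteError(
                    f"composition for region '{region}' sums to {total}, not 1"
                )
            if any(p < 0 for p in probs.values()):
                raise TilecyteError(f"negative probability in region '{region}'")
        for mapping in (self.background_level, self.noise_sd):
            if any(v < 0 for v in mapping.values()):
                raise TilecyteError("intensities and noise must be >= 0")
        for t, per_channel in self.signal_mean.items():
            if any(v < 0 for v in per_channel.values()):
                raise TilecyteError(f"negative signal mean for type '{t}'")


def region_compositions(
    overall: dict[str, float], lining: dict[str, float], lining_fraction: float
) -> dict[str, dict[str, float]]:
    """Region-wise compositions whose area-weighted mean equals ``overall``.

    Given the lining composition and the lining's share of the ROI area, the
    sub-lining composition is the unique vector making the expected overall
    composition (under uniform nucleus placement) match the target.
    """
    f = lining_fraction
    sub = {t: (overall[t] - f * lining[t]) / (1.0 - f) for t in overall}
    if any(p < -1e-12 for p in sub.values()):
        raise TilecyteError("lining composition too extreme for the overall target")
    return {"lining": dict(lining), "sub-lining": sub}


def comparator_config(**overrides) -> SimulationConfig:
    """Default non-inflamed comparator sample (67.0/19.1/13.9% DKK3/CD68/CD31)."""
    return SimulationConfig(**overrides)


def frozen_shoulder_config(**overrides) -> SimulationConfig:
    """Default disease-like sample (50.3/27.1/22.6% DKK3/CD68/CD31)."""
    cfg = SimulationConfig(**overrides)
    if "composition_by_region" not in overrides:
        cfg.composition_by_region = region_compositions(
            FROZEN_SHOULDER_COMPOSITION, _FROZEN_LINING, cfg.lining_fraction
        )
    return cfg


def make_region_mask(config: SimulationConfig) -> RegionMask:
    """Lining band along the top edge, sub-lining below; whole frame is ROI."""
    labels = np.full((config.image_height, config.image_width), SUBLINING, dtype=np.int8)
    labels[: config.lining_depth, :] = LINING
    return RegionMask(labels, pixel_size=config.pixel_size)


def place_nuclei(
    region_mask: RegionMask, n_nuclei: int, min_spacing: float, seed: int
) -> NucleusSet:
    """Place nuclei on ROI pixels by hard-core rejection sampling.

    Candidate positions are drawn uniformly over ROI pixel centres and
    accepted when at least ``min_spacing`` pixels from every accepted
    nucleus (and on a free pixel).  Ids are 1..n in placement order.  After
    ``10_000 * n_nuclei`` failed draws a
    :class:`~tilecyte.errors.PlacementInfeasibleError` reports how many were
    placed.
    """
    if min_spacing < 0:
        raise ValueError("min_spacing must be >= 0")
    rows, cols = np.nonzero(region_mask.roi)
    if len(rows) == 0:
        raise TilecyteError("region mask has no ROI pixels")
    if n_nuclei == 0:
        return NucleusSet.empty()

    rng = np.random.default_rng(seed)
    cell = max(min_spacing, 1.0)
    grid: dict[tuple[int, int], list[tuple[float, float]]] = {}
    occupied: set[tuple[int, int]] = set()
    placed: list[tuple[float, float]] = []
    s2 = min_spacing * min_spacing
    max_attempts = _MAX_ATTEMPTS_PER_NUCLEUS * n_nuclei
    attempts = 0
    while len(placed) < n_nuclei and attempts < max_attempts:
        attempts += 1
        k = int(rng.integers(len(rows)))
        r, c = float(rows[k]), float(cols[k])
        if (rows[k], cols[k]) in occupied:
            continue
        gi, gj = int(r // cell), int(c // cell)
        ok = True
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for pr, pc in grid.get((gi + di, gj + dj), ()):
                    if (pr - r) ** 2 + (pc - c) ** 2 < s2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if not ok:
            continue
        placed.append((r, c))
        occupied.add((rows[k], cols[k]))
        grid.setdefault((gi, gj), []).append((r, c))
    if len(placed) < n_nuclei:
        raise PlacementInfeasibleError(n_nuclei, len(placed), attempts)
    return NucleusSet(np.array(placed, dtype=float))


def assign_true_types(
    nuclei: NucleusSet, region_mask: RegionMask, config: SimulationConfig, seed: int
) -> pd.DataFrame:
    """Ground-truth table: per nucleus id, position, region and true type.

    Types are drawn independently per nucleus from the composition vector of
    the nucleus's region (a multinomial draw per region).
    """
    rng = np.random.default_rng(seed)
    px = nuclei.pixels()
    region_codes = region_mask.labels[px[:, 0], px[:, 1]]
    regions = [REGION_NAMES[int(c)] for c in region_codes]
    types = np.empty(len(nuclei), dtype=object)
    for region_name, probs in config.composition_by_region.items():
        idx = [i for i, r in enumerate(regions) if r == region_name]
        if not idx:
            continue
        names = list(probs)
        p = np.array([probs[t] for t in names], dtype=float)
        types[idx] = rng.choice(names, size=len(idx), p=p / p.sum())
    return pd.DataFrame(
        {
            "id": nuclei.ids,
            "row": nuclei.centroids[:, 0],
            "col": nuclei.centroids[:, 1],
            "region": regions,
            "true_type": types,
        }
    )


def _dapi_channel(nuclei: NucleusSet, config: SimulationConfig) -> np.ndarray:
    """Sum of isotropic Gaussian blobs (sd = nucleus_radius / 2, fixed peak)."""
    h, w = config.image_height, config.image_width
    out = np.zeros((h, w), dtype=float)
    sd = config.nucleus_radius / 2.0
    half = max(int(np.ceil(4 * sd)), 1)
    for r0, c0 in nuclei.centroids:
        ri = int(round(r0))
        ci = int(round(c0))
        rlo, rhi = max(ri - half, 0), min(ri + half + 1, h)
        clo, chi = max(ci - half, 0), min(ci + half + 1, w)
        rr = np.arange(rlo, rhi)[:, None] - r0
        cc = np.arange(clo, chi)[None, :] - c0
        out[rlo:rhi, clo:chi] += config.dapi_peak * np.exp(
            -(rr * rr + cc * cc) / (2 * sd * sd)
        )
    return out


def render_multiplex(
    nuclei: NucleusSet,
    truth: pd.DataFrame,
    region_mask: RegionMask,
    config: SimulationConfig,
    seed: int,
) -> MultiplexImage:
    """Render the multi-channel image for one sample.

    The DAPI channel is a sum of Gaussian blobs at the nucleus centroids.
    Each marker channel is its background level, plus the type-specific
    signal mean constant over each cell's footprint (the pixels of the
    nucleus's Voronoi tile), plus zero-mean Gaussian noise, clipped at zero.
    """
    unknown = set(truth["true_type"]) - set(config.signal_mean)
    if unknown:
        raise UnknownCellTypeError(f"unknown type(s) in ground truth: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    h, w = config.image_height, config.image_width
    stack = np.zeros((len(config.channel_names), h, w), dtype=float)

    if len(nuclei):
        tiles = voronoi_label(nuclei, region_mask).labels
        type_of = truth.set_index("id")["true_type"]
    for ci, cname in enumerate(config.channel_names):
        if cname == "DAPI":
            img = _dapi_channel(nuclei, config) if len(nuclei) else np.zeros((h, w))
            img = img + config.background_level.get("DAPI", 0.0)
        else:
            img = np.full((h, w), config.background_level[cname], dtype=float)
            if len(nuclei):
                # signal lookup table indexed by tile id (0 -> no signal)
                lut = np.zeros(len(nuclei) + 1, dtype=float)
                for nid in nuclei.ids:
                    lut[nid] = config.signal_mean[type_of.loc[nid]][cname]
                img = img + lut[tiles]
        sd = config.noise_sd.get(cname, 0.0)
        if sd > 0:
            img = img + rng.normal(0.0, sd, size=(h, w))
        stack[ci] = np.clip(img, 0.0, None)
    return MultiplexImage(stack, config.channel_names, pixel_size=config.pixel_size)


@dataclass(frozen=True)
class SampleBundle:
    """One simulated sample: image, region mask, nuclei and ground truth."""

    sample_id: str
    group: str
    image: MultiplexImage
    region_mask: RegionMask
    nuclei: NucleusSet
    truth: pd.DataFrame
    config: SimulationConfig


def simulate_sample(
    config: SimulationConfig, seed: int, sample_id: str = "sample", group: str = ""
) -> SampleBundle:
    """Simulate a single sample; all randomness derived from ``seed``."""
    rng = np.random.default_rng(seed)
    s_place, s_types, s_render = (int(x) for x in rng.integers(0, 2**31 - 1, size=3))
    mask = make_region_mask(config)
    nuclei = place_nuclei(mask, config.n_nuclei, config.min_spacing, s_place)
    truth = assign_true_types(nuclei, mask, config, s_types)
    image = render_multiplex(nuclei, truth, mask, config, s_render)
    return SampleBundle(sample_id, group, image, mask, nuclei, truth, config)


def simulate_study(
    config_comparator: SimulationConfig | None = None,
    config_disease: SimulationConfig | None = None,
    n_samples_per_group: int = 5,
    seed: int = 0,
) -> list[SampleBundle]:
    """Simulate a two-group study; per-sample seeds derive from ``seed``.

    Groups are named ``comparator`` and ``frozen_shoulder``; sample ids are
    ``<group>_<k>``.  The bundle is fully reproducible from (configs, seed).
    """
    if n_samples_per_group < 1:
        raise ValueError("need at least one sample per group")
    if config_comparator is None:
        config_comparator = comparator_config()
    if config_disease is None:
        config_disease = frozen_shoulder_config()
    rng = np.random.default_rng(seed)
    bundles = []
    for group, cfg in (
        ("comparator", config_comparator),
        ("frozen_shoulder", config_disease),
    ):
        for k in range(1, n_samples_per_group + 1):
            sample_seed = int(rng.integers(0, 2**31 - 1))
            bundles.append(
                simulate_sample(cfg, sample_seed, sample_id=f"{group}_{k}", group=group)
            )
    return bundles


def config_to_dict(config: SimulationConfig) -> dict:
    """Plain-python dict view of a config (YAML-serializable)."""
    d = asdict(config)
    d["channel_names"] = list(config.channel_names)
    return d


__all__ = [
    "SimulationConfig",
    "SampleBundle",
    "COMPARATOR_COMPOSITION",
    "FROZEN_SHOULDER_COMPOSITION",
    "region_compositions",
    "comparator_config",
    "frozen_shoulder_config",
    "make_region_mask",
    "place_nuclei",
    "assign_true_types",
    "render_multiplex",
    "simulate_sample",
    "simulate_study",
    "config_to_dict",
]
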