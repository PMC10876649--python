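"""End-to-end orchestration: simulate/load -> preprocess -> detect ->
tessellate -> type -> compose -> compare, with config capture and QC.

A run is driven by one YAML config and a master seed; every intermediate is
persisted to the output directory so any stage can be re-run or inspected in
isolation, and identical (config, seed) runs produce byte-identical CSVs.
Stage wall-times and warnings live only in ``qc.json``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .calling import call_tile_types, composition_table, tile_intensity_matrix
from .datatypes import (
    UNASSIGNED,
    DetectionParams,
    MultiplexImage,
    NucleusSet,
    RegionMask,
)
from .detect import detect_nuclei
from .errors import PipelineStageError, TilecyteError
from .prep import DegenerateChannelWarning, median_despeckle, normalize_channel
from .stats import cellularity, compare_compositions
from .synthetic import (
    SampleBundle,
    comparator_config,
    frozen_shoulder_config,
    simulate_study,
)
from .tessellate import assign_tile_regions, voronoi_label

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated view of a pipeline run configuration."""

    mode: str = "simulate"  # "simulate" | "images"
    simulate: dict = field(default_factory=dict)  # group config overrides
    samples: list[dict] = field(default_factory=list)  # images mode
    despeckle_radius: float = 0.5
    p_low: float = 1.0
    p_high: float = 99.0
    detection: DetectionParams = field(default_factory=DetectionParams)
    region_rule: str = "nucleus_position"
    aggregate_statistic: str = "mean"
    min_score: float = 0.0
    tie_order: list[str] | None = None
    seed: int = 0
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        cfg = cls(
            mode=raw.get("mode", "simulate"),
            simulate=raw.get("simulate", {}) or {},
            samples=raw.get("samples", []) or [],
            despeckle_radius=float(raw.get("despeckle", {}).get("radius", 0.5)),
            p_low=float(raw.get("normalize", {}).get("p_low", 1.0)),
            p_high=float(raw.get("normalize", {}).get("p_high", 99.0)),
            detection=DetectionParams(**raw.get("detect", {})),
            region_rule=raw.get("region_rule", "nucleus_position"),
            aggregate_statistic=raw.get("aggregate_statistic", "mean"),
            min_score=float(raw.get("min_score", 0.0)),
            tie_order=raw.get("tie_order"),
            seed=int(raw.get("seed", 0)),
            raw=raw,
        )
        if cfg.mode not in ("simulate", "images"):
            raise TilecyteError(f"unknown mode '{cfg.mode}'")
        if cfg.mode == "images":
            if not cfg.samples:
                raise TilecyteError("images mode requires a 'samples' list")
            for s in cfg.samples:
                for key in ("image", "mask"):
                    p = Path(s.get(key, ""))
                    if not p.exists():
                        raise TilecyteError(
                            f"sample '{s.get('id', '?')}': missing {key} path '{p}'"
                        )
        return cfg

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.raw, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


@dataclass
class SampleResult:
    """Analysis outputs for one sample."""

    sample_id: str
    group: str
    nuclei: NucleusSet
    tile_regions: pd.DataFrame
    types: pd.DataFrame
    composition: pd.DataFrame
    cellularity: pd.DataFrame
    qc: dict


def analyse_sample(
    image: MultiplexImage,
    region_mask: RegionMask,
    config: RunConfig,
    sample_id: str = "sample",
    group: str = "",
    nuclei: NucleusSet | None = None,
) -> SampleResult:
    """Run preprocessing through composition for a single sample.

    ``nuclei`` bypasses detection when supplied (e.g. external centroids).
    """
    qc: dict = {"sample": sample_id, "warnings": [], "timings_s": {}}

    def stage(name):
        class _Timer:
            def __enter__(self_):
                self_.t0 = time.perf_counter()

            def __exit__(self_, exc_type, exc, tb):
                qc["timings_s"][name] = round(time.perf_counter() - self_.t0, 4)
                if exc is not None and not isinstance(exc, PipelineStageError):
                    raise PipelineStageError(name, sample_id, exc) from exc
                return False

        return _Timer()

    with stage("preprocess"):
        dapi = median_despeckle(image.dapi, config.despeckle_radius)
        markers = []
        roi = region_mask.roi
        qc["normalization_quantiles"] = {}
        for name in image.marker_names:
            ch = median_despeckle(image.channel(name), config.despeckle_radius)
            q_low, q_high = np.percentile(
                ch.values[roi], [config.p_low, config.p_high]
            )
            qc["normalization_quantiles"][name] = [float(q_low), float(q_high)]
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always", DegenerateChannelWarning)
                markers.append(
                    normalize_channel(ch, region_mask, config.p_low, config.p_high)
                )
            qc["warnings"] += [str(w.message) for w in caught]

    with stage("detect"):
        if nuclei is None:
            nuclei = detect_nuclei(dapi, region_mask, config.detection)
        qc["nucleus_count"] = len(nuclei)

    with stage("tessellate"):
        tiles = voronoi_label(nuclei, region_mask)
        tile_regions = assign_tile_regions(
            tiles, region_mask, nuclei, rule=config.region_rule
        )
        qc["tile_count"] = tiles.n_tiles
        qc["mean_tile_area_px"] = float(tiles.tile_areas().mean())

    with stage("type"):
        matrix = tile_intensity_matrix(tiles, markers, config.aggregate_statistic)
        tie_order = config.tie_order or list(matrix.columns)
        types = call_tile_types(
            matrix,
            min_score=config.min_score,
            tie_order=tie_order,
            regions=tile_regions.set_index("tile_id")["region"],
        )
        qc["unassigned_fraction"] = float((types["called_type"] == UNASSIGNED).mean())

    with stage("compose"):
        comp = composition_table(types, sample_id, type_names=list(matrix.columns))
        cells = cellularity(nuclei, region_mask)

    return SampleResult(
        sample_id, group, nuclei, tile_regions, types, comp, cells, qc
    )


def _load_samples(config: RunConfig) -> list[SampleBundle]:
    if config.mode == "simulate":
        sim = config.simulate
        n_per_group = int(sim.get("n_samples_per_group", 5))
        cfg_c = comparator_config(**sim.get("comparator", {}))
        cfg_d = frozen_shoulder_config(**sim.get("disease", {}))
        return simulate_study(cfg_c, cfg_d, n_per_group, seed=config.seed)
    bundles = []
    for s in config.samples:
        image = tio.read_multiplex_tiff(s["image"], s.get("channels_yaml"))
        mask = tio.read_region_mask(s["mask"])
        bundles.append(
            SampleBundle(
                sample_id=str(s.get("id", Path(s["image"]).stem)),
                group=str(s.get("group", "")),
                image=image,
                region_mask=mask,
                nuclei=None,
                truth=None,
                config=None,
            )
        )
    return bundles


def run_pipeline(raw_config: dict, out_dir) -> dict:
    """Execute the full pipeline and write all outputs to ``out_dir``.

    Returns a summary dict with the combined composition table, the
    cellularity table, the group-comparison table (when two groups are
    present) and the QC report.
    """
    config = RunConfig.from_dict(raw_config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    tio.write_yaml(config.raw, out / "run_config.yaml")

    bundles = _load_samples(config)
    results: list[SampleResult] = []
    for b in bundles:
        logger.info("analysing sample %s", b.sample_id)
        res = analyse_sample(
            b.image, b.region_mask, config, sample_id=b.sample_id, group=b.group
        )
        sdir = out / b.sample_id
        sdir.mkdir(exist_ok=True)
        tio.write_nuclei_csv(res.nuclei, sdir / "nuclei.csv")
        tio.write_csv_with_header(
            res.tile_regions, sdir / "tile_regions.csv", comment=f"config={chash}"
        )
        tio.write_csv_with_header(
            res.types, sdir / "tile_types.csv", comment=f"config={chash}"
        )
        tio.write_csv_with_header(
            res.composition, sdir / "composition.csv", comment=f"config={chash}"
        )
        if b.truth is not None:
            b.truth.to_csv(sdir / "ground_truth.csv", index=False, float_format="%.10g")
        results.append(res)

    comp_all = pd.concat(
        [r.composition.assign(group=r.group) for r in results], ignore_index=True
    )
    tio.write_csv_with_header(
        comp_all, out / "composition_combined.csv", comment=f"config={chash}"
    )
    cell_all = pd.concat(
        [r.cellularity.assign(sample=r.sample_id, group=r.group) for r in results],
        ignore_index=True,
    )
    tio.write_csv_with_header(
        cell_all, out / "cellularity.csv", comment=f"config={chash}"
    )

    comparison = None
    groups = sorted({r.group for r in results if r.group})
    if len(groups) == 2:
        extra = {}
        for region in ("lining", "sub-lining", "total"):
            vals = {
                g: [
                    float(
                        r.cellularity.set_index("region").loc[region, "count"]
                    )
                    for r in results
                    if r.group == g
                ]
                for g in groups
            }
            extra[f"cellularity_{region}"] = (vals[groups[0]], vals[groups[1]])
        comparison = compare_compositions(
            comp_all, groups=(groups[0], groups[1]), extra_endpoints=extra
        )
        tio.write_csv_with_header(
            comparison, out / "comparison.csv", comment=f"config={chash}"
        )

    qc = {
        "config_hash": chash,
        "samples": [r.qc for r in results],
    }
    with open(out / "qc.json", "w") as fh:
        json.dump(qc, fh, indent=2, sort_keys=True)

    return {
        "composition": comp_all,
        "cellularity": cell_all,
        "comparison": comparison,
        "qc": qc,
        "results": results,
    }


__all__ = ["RunConfig", "SampleResult", "analyse_sample", "run_pipeline"]
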