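# tilecyte

Voronoi tile-based cell-type quantification for multiplexed
immunofluorescence tissue images.

## The problem

Multiplexed immunofluorescence (e.g. iterative stain–image–bleach platforms)
produces a nuclear channel (DAPI) plus one channel per cell-type marker —
here CD31 (vascular endothelium), CD68 (macrophages) and DKK3 (fibroblasts)
in joint-capsule tissue, whose thin synovial-like **lining** overlies a
collagen-rich **sub-lining**. Counting cells per type in tissue is
complicated by large differences in cell size and shape. `tilecyte`
implements the tile-based alternative: subdivide the ROI into one "tile"
per nucleus with the Voronoi rule, so that every cell contributes exactly
one unit regardless of its size, then call one type per tile from marker
intensity.

## The method

For nuclei with centroids $c_1,\dots,c_n$, the tile of nucleus $i$ is the
set of ROI pixels $p$ with $\lVert p - c_i\rVert \le \lVert p -
c_j\rVert\ \forall j$ (ties to the smallest id) — the discrete Voronoi
tessellation, computed exactly on the pixel grid and clipped by the ROI
mask. Marker channels are despeckled (median filter, radius 0.5 → 5-pixel
cross) and rescaled by robust ROI percentiles,
$x \mapsto \mathrm{clip}\big((x - q_1)/(q_{99} - q_1),\,0,\,1\big)$, so the
per-tile argmax across channels of the aggregated normalized intensity
(mean by default) is scale-free: each tile is called CD31+, CD68+ or DKK3+.
Compositions are tabulated per region (lining / sub-lining / combined),
cellularity is counted per region (cells/mm²), chromogenic stains are
quantified as % ROI area above threshold normalized to nuclei counts, and
two-group endpoints are compared with a two-sided Mann-Whitney U test whose
p-value is exact (full enumeration, tie-aware, reflection rule) for pooled
n ≤ 20.

Because studies of this kind rarely deposit raw images, the package ships a
synthetic tissue generator (`tilecyte.synthetic`): hard-core nucleus
placement, region-dependent cell-type draws, Gaussian-blob DAPI, and
tile-constant marker signal plus background and Gaussian noise — with full
per-nucleus ground truth, so the whole pipeline is testable end to end.

## Worked example

```python
from tilecyte import comparator_config, simulate_sample, analyse_sample
from tilecyte.pipeline import RunConfig

config = comparator_config(image_height=256, image_width=256, lining_depth=32,
                           n_nuclei=250, min_spacing=8)
bundle = simulate_sample(config, seed=7, sample_id="roi1", group="comparator")
result = analyse_sample(bundle.image, bundle.region_mask, RunConfig.from_dict({}),
                        sample_id="roi1")
print(result.composition[result.composition.region == "combined"].to_string(index=False))
```

prints

```
sample   region       type  count  proportion_pct  n_tiles
  roi1 combined       CD31     36            14.4      250
  roi1 combined       CD68     48            19.2      250
  roi1 combined       DKK3    166            66.4      250
  roi1 combined unassigned      0             0.0      250
```

All 250 nuclei were detected, tessellated into 250 tiles, and typed; the
recovered proportions sit within binomial sampling error of the configured
comparator composition (67.0% DKK3+, 19.1% CD68+, 13.9% CD31+).
`result.cellularity` gives nucleus counts and densities per region, and the
`unassigned` row is empty because the default calling threshold is 0
(exhaustive three-way assignment).

The same analysis is available from the shell:

```sh
tilecyte simulate --config sim.yaml --out data/ --seed 1
tilecyte run --config run.yaml --out results/ --seed 1
```

`tilecyte run` persists every intermediate (nuclei CSVs, tile label TIFFs,
type/composition/comparison CSVs, `qc.json`) and identical config + seed
reruns are byte-identical.

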