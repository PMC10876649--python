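# Methods

## Tile model

The unit of quantification is the *tile*: the set of ROI pixels nearer (in
Euclidean distance between pixel centres) to one nucleus centroid than to
any other. One tile per nucleus, tile borders equidistant between
neighbouring nuclei, every ROI pixel in exactly one tile. This normalizes
for cell size: a large fibroblast and a small endothelial cell each
contribute one tile. The tessellation is computed discretely — per-pixel
nearest centroid on the grid — rather than by clipping Voronoi polygons.
The discrete form is exact for arbitrary ROI masks, needs no geometric
predicates, and matches the downstream use of tiles as pixel sets. Exact
ties go to the smallest nucleus id so the labelling is bit-reproducible.
Internally a KD-tree supplies the nearest centroid; any pixel whose two
nearest centroids are within relative distance 1e-9 is re-resolved by a
brute-force scan with the stated tie rule, so the fast path can never
disagree with the definition. No maximum tile radius is imposed; in sparse
regions tiles can be large.

Distances assume isotropic pixels and are measured in pixel units; the
pixel size (µm/px) enters only in area/density conversions.

## Preprocessing and the typing rule

Marker channels are optionally despeckled with a median filter. The
footprint for fractional radii follows the common imaging convention of an
inflated disk (offsets with `dr² + dc² ≤ r² + 1`, `r = max(radius, 0.5)`):
radius 0.5 gives the 5-pixel cross (centre + 4-neighbours). Radius 0 is the
identity. Borders reflect.

Each marker channel is then rescaled over the ROI:
`clip((x − q_low) / (q_high − q_low), 0, 1)` with `q_low`/`q_high` the 1st
and 99th linear-interpolation percentiles of ROI pixel values (both
percentiles configurable). Robust percentile scaling makes channels with
different dynamic ranges comparable before the cross-channel argmax, and is
invariant to per-channel affine transforms `a·x + b, a > 0` — a property the
test suite asserts end to end. Percentiles are computed per ROI, not per
slide; results can differ under per-slide scaling. A channel constant over
the ROI is degenerate: it is returned as all zeros with a warning recorded
in the QC log. Re-normalizing an already-normalized channel is an exact
fixed point when the percentile positions `p·(n−1)/100` land on data points
(e.g. ROI sizes `n ≡ 1 (mod 100)` at the default 1/99); otherwise the
clipping kink perturbs interpolated percentiles by at most the local
order-statistic gap.

Typing aggregates each normalized marker over each tile's pixels — mean by
default (robust to single hot pixels), median and max selectable — and
calls the argmax channel. DAPI is excluded from the call: it marks all
cells. Exact ties go to the earliest channel in a configurable `tie_order`
(default: channel order); ties have measure zero under noise but must be
deterministic. A `min_score` threshold can leave dim tiles `unassigned`;
the default 0 assigns every tile, the exhaustive three-way regime in which
reported compositions sum to 100%.

## Nucleus detection

Detection is a classical deterministic chain: Gaussian smoothing
(`smoothing_sd`, default 1 px) → foreground by Otsu over ROI pixels (or a
fixed threshold) → connected components with area ≥ `min_blob_area`
(default 5 px) → watershed splitting of merged blobs seeded at per-component
local maxima separated by ≥ `min_distance` (default 3 px) → one
intensity-weighted centroid per fragment. Centroids are ordered
lexicographically by (row, col) and ids assigned 1..n, so detection is
rank-stable. In the rare event that two fragments' centroids round to the
same pixel, the later one in that order is dropped, preserving the
one-nucleus-per-pixel invariant. A flat DAPI channel yields an empty
result (not an error); an empty ROI is an error. Pre-computed centroids
(CSV `id,row,col`) can be substituted for detection at any point, so
tessellation and typing are testable independently of detection quality.

## Scalar quantifications and statistics

*Cellularity*: nuclei are counted in the region at the pixel containing
their centroid; densities are counts over region area
(`pixels × pixel_size² / 10⁶` mm²). *Percent-area immunopositivity* (for
chromogenic, DAB-style stains): `100 × |{ROI pixels > threshold}| / |ROI|`,
with Otsu over the ROI as the default threshold (original thresholds of
such analyses are typically unrecoverable) and an explicit override;
positive area is also reported normalized to the nuclei count (µm² per
nucleus) since % area and per-nucleus normalization are both conventional
and combine ambiguously — both metrics are emitted.

Group comparison uses the two-sided Mann-Whitney U test,
`U = #{(i,j): aᵢ > bⱼ} + ½·#ties`. For pooled n ≤ 20 the p-value is exact:
all `C(n₁+n₂, n₁)` assignments of the pooled values are enumerated and the
two-sided p is the probability mass of assignments with
`|U − n₁n₂/2| ≥ |U_obs − n₁n₂/2|` (the reflection rule, correct under
asymmetric tie distributions, unlike doubling a one-sided tail). Beyond
pooled n = 20 a normal approximation with tie correction and 0.5 continuity
correction is used; the switch point is chosen because group sizes of 5–9
per group — typical for tissue-donor studies — sit comfortably in the exact
regime, where exactness is cheap (≤ 184 756 assignments). Unadjusted
p-values are the primary output; a Benjamini-Hochberg column is opt-in.

## Synthetic tissue generator

The generator emulates the structure this pipeline is designed for, with
per-nucleus ground truth:

* **Geometry** — 512×512 px at 0.5 µm/px by default; the lining is a
  64-px band along the top edge (12.5% of the ROI), the rest sub-lining,
  the whole frame ROI. The fixed-depth band is the simplest geometry
  preserving the lining/sub-lining dichotomy.
* **Nuclei** — 1000 per ROI by default (the scale of real ROIs of this
  tissue, which average on the order of a thousand tiles), placed by
  rejection sampling with a hard-core spacing of 8 px (cap: 10 000·n
  attempts, after which a "placement infeasible" error reports the achieved
  count). Reproducible, simple, and visually non-overlapping.
* **Types** — each nucleus draws its type from its region's composition
  vector. Defaults: comparator group overall 67.0/19.1/13.9%
  DKK3/CD68/CD31, disease-like group 50.3/27.1/22.6%. The lining vectors
  (comparator 0.55/0.35/0.10; disease 0.38/0.45/0.17) encode CD68
  enrichment in the lining and CD31 enrichment in the sub-lining; the
  sub-lining vector is solved so the area-weighted mean equals the overall
  target exactly.
* **Image** — DAPI is a sum of isotropic Gaussian blobs
  (sd = nucleus_radius/2 = 1.5 px, peak 200) plus noise (sd 5); each marker
  channel is background 10 plus the type's signal (own marker 60, others 0)
  constant over the cell's Voronoi tile, plus Gaussian noise sd 10 (SNR 6),
  clipped at zero (photon-like non-negative counts). Arbitrary linear
  intensity units. Tile-constant signal is the simplest model under which
  the argmax typing rule is Bayes-optimal, which is what makes recovery
  tests meaningful.

What the generator does **not** emulate: optics (PSF, channel
bleed-through, illumination gradients), multi-round registration error,
autofluorescence texture, nuclear shape variation, 3-D structure. Passing
recovery tests therefore demonstrates correctness of the algorithmic chain,
not robustness to those real-data artefacts.

## Pipeline, determinism and problem sizes

`tilecyte run` executes simulate/load → preprocess → detect → tessellate →
type → compose → compare from one YAML config and a master seed; per-sample
seeds derive deterministically from it. Every intermediate is persisted;
CSVs embed a config hash in a comment header and are written with fixed
float formatting, so identical (config, seed) runs are byte-identical.
Stage wall-times and warnings live only in `qc.json`. Any stage failure
aborts naming the stage and sample; partial outputs are retained.

The test suite and the acceptance script use full-scale samples (512×512,
1000 nuclei) for the recovery checks — about one second per sample — and
down-scaled samples (128–256 px, 80–250 nuclei) for unit tests; the Voronoi
oracle checks use ≤ 64×64 grids with ≤ 30 centroids where exhaustive
scanning is instant.

## Known limitations

* Region assignment of a tile uses the nucleus position by default (a
  cell's identity is where its nucleus sits); `majority_pixel` is available
  since the convention is not standardized.
* Geodesic (ROI-constrained) distances are not supported; tiles can cross
  narrow background gaps in pathological masks.
* The detector is tuned for blob-like nuclear stains; densely touching or
  irregular nuclei need externally supplied centroids.
* Exact Mann-Whitney enumeration is O(C(n,n₁)); pooled n > 20 silently
  switches to the (tie- and continuity-corrected) normal approximation.
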