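# Methods

This note documents the models, numerical choices and limitations behind
`puncta_coloc`. Coordinates throughout are 0-based `(row, col)` with the
origin at the top-left pixel; `x` is the column and `y` the row.

## Image handling

All analysis runs on an 8-bit RGB working form. 16-bit input is converted
with the fixed map `v -> floor(v / 256)` by default: it is deterministic
and makes intensities comparable across images, which matters whenever a
single fixed threshold is applied to a whole experiment. A `minmax` mode
(per-plane `[min, max] -> [0, 255]` stretch, the display-range behavior of
most viewers) is available behind a flag for users whose acquisition
pipeline assumes it; the two modes give different absolute cutoff meanings,
so the choice is recorded in the run configuration.

Z-stacks are collapsed by grouped maximum projection: planes are
partitioned in z-order into consecutive runs of `zproj_group` planes and
each run is max-projected per channel, so a 15-plane stack with groups of 3
yields 5 projections, each analyzed as an independent image. A trailing
incomplete group is projected from its remaining planes rather than
dropped — silently losing planes seemed worse — and is flagged in the log so
users can exclude those rows downstream.

Multi-page TIFFs are interpreted with a simple heuristic: an axis of length
≤ 4 is channels, a longer page axis is z. Ambiguous single-channel stacks
of ≤ 4 planes are therefore read as channels; store such data as
`(z, c, h, w)` TIFFs to be explicit. Proprietary microscope formats
(CZI/LIF/ND2) are out of scope; convert upstream.

## Preprocessing (off by default)

Because these operations alter the data that thresholding sees, nothing is
applied unless requested, and the resolved parameters are echoed into the
output directory with every run.

* **Background subtraction** estimates the background by grayscale
  morphological opening with a disk of radius `rolling_radius` (default
  50 px, the common plugin default) and subtracts it, clipping at zero. A
  disk opening is used rather than the original paraboloid rolling-ball
  kernel; for spot-like foreground on slowly varying background the
  difference is immaterial once thresholding follows, and the opening is
  exactly reproducible.
* **Gaussian blur** (default sigma 1.0 px when enabled) uses a normalized
  kernel with reflective boundaries, so constants are preserved and
  interior mass is conserved.
* **Brightness normalization** maps `[min, q]` linearly onto `[0, 255]`
  where `q` is the `1 - saturated_fraction` lower order statistic (default
  fraction 0.0035, a common enhance-contrast default); values above `q`
  saturate. Applying one fraction to all images equalizes the percentage of
  saturated pixels across an experiment. Constant planes map to zero.

## Thresholding

Foreground is `intensity >= cutoff` (lower-bound convention), so cutoff 0
selects everything and masks shrink monotonically as the cutoff rises.
Available modes: per-image manual values, one fixed value for all images,
values re-loaded from a recorded threshold table (`thresholds.csv`, written
on every run — re-running with it reproduces masks and summary
byte-for-byte), Otsu's method (exhaustive 256-bin between-class-variance
maximization; ties resolve to the lowest cutoff), and the statistical
detector below. Interactive machine-learning thresholding is deliberately
not included; the statistical detector and Otsu cover the unsupervised
use cases.

### Statistical spot detector

An original implementation of component-tree style spot detection driven by
a contrast z-score; it follows the parameter semantics common in synapse
detection tools but is not a port of any of them, and numerical parity with
SynQuant is not claimed (its order-statistics refinements are omitted).

Candidates are the connected components of every super-level set as the
cutoff sweeps all 256 intensity levels descending. A candidate is scored

    z = (mean_inside - mean_ring) / (noise_std * sqrt(1/n_in + 1/n_ring))

where the ring is the component's 2-px dilation shell. Geometric filters
are applied before scoring: area within `[min_object_size,
max_object_size]` (defaults 10–100 px), bounding-box fill ≥
`min_object_fill` (default 0.5), bounding-box elongation ≤
`max_width_height_ratio` (default 4). Acceptance requires
`z >= z_score_threshold` (default 10). Among nested or overlapping
candidates the best-scoring one is kept — implemented as greedy selection
in descending z with ties broken toward smaller area, then position —
so accepted objects are pairwise disjoint. `noise_std` defaults to 12
intensity units; `"auto"` substitutes the robust estimate
`1.4826 * median(|plane - median|)`. With the defaults, pure
Gaussian-noise planes (mean 30, sd 12, 512²) produce zero accepted objects
in ≥ 95% of seeded runs; the z = 10 bar is simply far beyond what noise
components achieve.

## Puncta detection

Connected components (8-connectivity by default, the particle-analyzer
convention; 4 available) with a per-channel size filter (default min 4 px,
no upper bound — both are user inputs in practice). Each punctum records
centroid, area, bounding box, circularity `4*pi*A / P^2` with the perimeter
`P` counted as background-exposed pixel faces (clipped to 1.0), and the
equivalent-disk radius `sqrt(A/pi)`. The equivalent-disk definition is the
natural radius for near-circular puncta and is the one used by the circular
colocalization mode; a Feret-based radius would differ for elongated
objects, which the circular mode is unsuited to anyway. Merged puncta are
not watershed-split: the circular mode assumes well-separated, roughly
circular objects, and users should verify circularity on their data.

## Colocalization

**Circular mode.** Every red/green pair with center distance strictly less
than the sum of equivalent radii counts; tangency is not an overlap. The
lens area uses the sector-minus-triangle closed form; when one disk
contains the other (`d <= |r1 - r2|`, where that construction is undefined)
the smaller disk's full area is returned. The recorded colocalization
centroid is the midpoint of the chord line — the point at distance `d1`
from the first center along the center line — which is deterministic and
always inside the lens. Counting is pairwise: one red punctum overlapping
two greens contributes two colocalizations, and no deduplication is
attempted; the mode label is carried in the summary so cross-mode
comparisons are explicit. Circular mode is restricted to two channels;
three-channel requests are routed to pixel mode with a warning.

**Pixel mode.** Logical AND of the (size-filtered) channel masks, two or
three channels; overlap components of at least `coloc_min_size` pixels
(default 1) are counted. On perfect-disk puncta the two modes provably
agree on the count, which the test suite asserts on generated fixtures.

**ROI.** Analysis can be restricted to a circle (e.g. a 301-px-radius disk
around a cultured neuron's soma), an arbitrary mask image, or the whole
image; mask pixels outside the ROI are cleared before detection, and the
ROI pixel area is recorded in the summary.

## Benchmark simulator

The generator emulates fluorescence synapse images with known ground truth.
Each image pair carries 1000 anchors — 334 red-only, 333 green-only, 333
double-labeled — placed uniformly at random without bounding-box collision
(rejection sampling with a coarse-grid occupancy index; bounded retries,
then a hard error). "Both" anchors use a single shared top-left anchor
point for the red and the green paste, so the realized overlap depends on
the template footprints and amplitude jitter — this is what keeps benchmark
recall/precision from being trivially pinned at 1.0 after thresholding.

The default template is a parametric isotropic Gaussian spot: sigma 1.5 px,
9×9 support, peak amplitude 180 (8-bit) with ±20% per-paste jitter, values
chosen to resemble diffraction-limited synaptic puncta at typical confocal
sampling. A template-bank mode accepts small user-supplied images for
workflows that paste real puncta. Background pixels are drawn from
`Normal(base_mean * m, base_std * m)` for multiplier
`m ∈ {0, 0.25, 0.5, 0.75, 1.0}`, rounded half-to-even and clipped to
[0, 255]; defaults `base_mean = 30`, `base_std = 12` make `m = 1` an
excessive background relative to spot amplitude while `m ≤ 0.75` resembles
acceptable experimental data. Templates combine with background by
per-pixel maximum. The default dataset is 20 images per level, 100 pairs,
written as 2-channel TIFFs with per-image truth tables and a manifest;
per-image seeds derive from the master seed, so a dataset is byte-identical
across runs.

What the simulator does **not** emulate: real puncta shape variability
beyond amplitude jitter, spatially correlated background (cell bodies,
neurites, out-of-focus haze), chromatic offset between channels, and
intensity histograms tied to any particular acquisition. Benchmark results
therefore demonstrate pipeline correctness and noise robustness under
controlled conditions, not expected performance on any given microscope's
data.

## Evaluation

A detected colocalization matches a double-labeled truth position (center
= anchor + template half-extent) when their distance is within the
tolerance, default the template half-diagonal (≈ 6.4 px for 9×9) so any
detection inside the pasted footprint counts. Matching is greedy
nearest-first with one-to-one constraints, ties broken by detection index —
simpler than optimal assignment and indistinguishable from it at these
densities. Recall and precision follow the standard definitions and are
defined as 0 (with a logged warning) when a denominator is 0. Per-level
aggregation reports mean ± standard error over the images at each noise
multiplier.

The packaged end-to-end benchmark (`puncta_coloc.benchmark.run_benchmark`)
tunes one fixed per-channel cutoff with Otsu on a zero-noise image, applies
it across all 100 images in pixel mode, and scores each image. At the
default scale this yields recall 1.00 at every multiplier and precision
declining from 1.00 to ≈ 0.93 at `m = 1.0`, where background fluctuations
start crossing the fixed cutoff in both channels at the same locations —
the expected degradation pattern once background becomes excessive.

## Pipeline and reproducibility

An experiment directory must contain at least one subfolder of images;
subfolder names become the `group` column (organizational only). One
unreadable image is skipped with a logged warning, never aborting the run.
Every run writes `summary.csv`, `thresholds.csv`, the resolved
`config.yaml` and `run.log` at the top of the output directory, plus
per-projection puncta/colocalization tables and `_colocs` overlay images
(white dots of radius 2 px by default at each counted synapse) per group.
Identical configuration and inputs give byte-identical tables; stochastic
components (the simulator) are seeded explicitly.

Problem sizes used by the test suite and the acceptance script — 512²
benchmark images, 20 per noise level, 100 Monte-Carlo geometry pairs at 10⁷
samples, 50 noise seeds for the false-positive check — are the package's
default study conditions and complete in a few minutes on one CPU.

## Known limitations

* 2-D only: z-stacks are analyzed as independent projections; no 3-D
  reconstruction or volumetric colocalization.
* Object-based counting only: no intensity-correlation measures
  (Pearson/Manders), which answer a different question.
* No watershed splitting of merged puncta; dense tissue with touching
  puncta will undercount.
* The circular mode's accuracy degrades with non-circular puncta; check
  circularity values in the puncta tables before trusting it.
* Downstream statistics (group comparisons, mixed models) are out of
  scope; the summary tables are designed to feed standard tools.
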