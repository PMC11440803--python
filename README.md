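# puncta-coloc

Object-based colocalization analysis of synaptic puncta in multi-channel
fluorescence microscopy images, with a simulated-synapse benchmark generator
and a recall/precision evaluation harness.

## The problem

Counting structural synapses in light microscopy is done by staining a
pre-synaptic marker (e.g. VGluT1, Bassoon, VGAT) in one channel and a
post-synaptic marker (e.g. PSD95, Homer1, gephyrin) in another, then
counting the places where puncta — small, roughly circular fluorescent
spots — from the two channels overlap. Each red/green overlap is a proxy
for one synapse. `puncta-coloc` automates the full path from raw images
(TIFF/PNG/BMP, 8- or 16-bit, single planes or z-stacks) to per-image synapse
counts, and ships the synthetic benchmark needed to measure how well the
detection pipeline performs under increasing background noise.

## The method

For every image: grouped maximum-intensity z-projection → 8-bit RGB working
form → optional denoising (rolling-ball background subtraction, Gaussian
blur) and brightness normalization → per-channel thresholding → optional
region-of-interest restriction → connected-component puncta detection with
per-channel size filters → colocalization counting in one of two modes:

* **Circular approximation.** Each punctum is reduced to a disk with its
  equivalent radius $r = \sqrt{A/\pi}$ at its centroid. A red/green pair
  with center distance $d < r_1 + r_2$ is one colocalization; its area is
  the circle–circle lens, computed in closed form with
  $d_1 = (d^2 + r_1^2 - r_2^2)/2d$, $d_2 = d - d_1$,
  $h = \sqrt{r_1^2 - d_1^2}$:

  $$A_\cap = r_1^2 \arccos(d_1/r_1) + r_2^2 \arccos(d_2/r_2) - d\,h$$

  (the two sectors minus the two triangles outside the overlap).
* **Pixel overlap.** The logical AND of the binary channel masks; each
  connected overlap component is one colocalization. Supports a third
  (blue) channel.

Thresholding modes: per-image manual values, one fixed value for all
images, recorded values re-loaded from a previous run (bit-exact
reproduction), Otsu's automatic method, and a statistical spot detector
that sweeps intensity cutoffs from high to low (component-tree style) and
accepts a candidate object only if its contrast z-score against a 2-px
surrounding ring reaches a threshold and it passes size, fill and
elongation filters.

The benchmark simulator pastes Gaussian-spot templates at 1000 known
anchors per image (334 red-only, 333 green-only, 333 double-labeled, i.e.
667 red and 666 green puncta with 333 true synapses) onto Gaussian-noise
backgrounds whose mean and standard deviation scale with a noise multiplier
in {0.00, 0.25, 0.50, 0.75, 1.00}; 20 images per level, 100 in total.
Detections are scored against ground truth with greedy one-to-one matching:
recall = TP/(TP+FN), precision = TP/(TP+FP).

## Worked example

Generate a small benchmark, analyze it with a fixed threshold, and score it:

```bash
puncta-coloc simulate dataset --images-per-level 2 --multipliers 0.0,0.5 \
    --image-size 256 --counts 60,60,60 --seed 3
mkdir -p exp/sim && cp dataset/*.tif exp/sim/
puncta-coloc run exp out --threshold fixed --fixed-value 60,60 --mode pixel
puncta-coloc evaluate dataset out eval.csv
```

which prints

```
 multiplier  n_images  recall_mean  recall_sem  precision_mean  precision_sem
        0.0         2          1.0         0.0             1.0            0.0
        0.5         2          1.0         0.0             1.0            0.0
```

— at these low noise levels every one of the 60 true synapses per image is
recovered (recall 1.0) with no spurious detections (precision 1.0).
`out/summary.csv` holds one row per analyzed projection with the red/green
puncta counts, the colocalization count, the thresholds used and the ROI
area; `out/<group>/` holds per-puncta tables and a `*_colocs.png` feedback
overlay with a white dot at every counted synapse. Re-running with
`--threshold file --threshold-file out/thresholds.csv` reproduces
`summary.csv` byte-for-byte.

The same analysis is available as a library:

```python
from puncta_coloc.benchmark import run_benchmark
per_image, per_level, cutoffs = run_benchmark()
```

At the default benchmark scale (512×512, 1000 anchors, 20 images per noise
level) the fixed-threshold pipeline holds recall 1.00 across all noise
multipliers while precision falls from 1.00 (no background) to 0.93 at the
highest noise level — detection quality degrades only once the background
becomes excessive.

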