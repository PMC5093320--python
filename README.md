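# mtalign

Microtubule (MT) organization follows cell shape in epithelial tissues:
as a cell's apical surface elongates, its sub-apical MTs align with each
other and with the cell's long axis. `mtalign` implements both
computational halves of that story:

* a **stochastic simulator** of MT self-organization — dynamic-instability
  polymers (Gillespie-exact continuous-time Markov chain, rates α, β, α′,
  β′) nucleated from seeds on the boundary of a small 2D cell, with
  angle-dependent collision rules: below a critical angle θ_c = 30° a
  colliding tip *zips* parallel to the obstacle (forming bundles), above it
  it crosses another MT (catastrophe with probability p_cat = 0.01) or
  undergoes catastrophe at the cell boundary;
* an **image-analysis pipeline** that quantifies alignment in fluorescence
  images: per-cell gradient direction histograms (5×5 Sobel pair, 22%
  magnitude threshold, 4° bins, 90° rotation onto filament directions)
  fitted with an axial von Mises distribution. The fit's σ is the **MTSD**
  ("MT standard deviation", 90° = unaligned) and the acute angle between
  the fitted mean direction μ and the cell's long axis (from a moment
  ellipse fit of its mask) is the **MTDEV**;
* a **synthetic-data generator** (line images with known angular spread,
  rasterized simulation output, tiled cell fields) so the simulator and the
  quantifier validate each other without any external data.

The package is a library first (`import mtalign`, see `examples/`), with a
thin `mtalign` command-line tool (`simulate`, `sweep`, `quantify`, `synth`,
`validate`) for shell use.

## Worked example

`examples/04_quantify_synthetic_image.py` draws 100 straight filaments
with angular spread σ = 30° in a cell of eccentricity 0.8 and runs the
pipeline plus the independent Fourier cross-check:

```
generating sigma (truth):        30.0 deg
ground-truth MTSD of the lines:  29.8 deg
pipeline MTSD (Sobel histogram): 30.3 deg
Fourier cross-check MTSD:        29.8 deg
cell eccentricity from mask:     0.800
MT main direction / MTDEV:       174.6 / 5.4 deg
```

The pipeline recovers the length-weighted spread of the filaments actually
drawn (29.8°) to half a degree, and the spectral estimate agrees — the
estimator chain is unbiased on known-truth images.

`examples/02_simulate_single_cell.py` runs the full collision rules in a
cell of eccentricity 0.9 (492 nm wide) and prints, among other things:

```
MTSD  (alignment, 90 = unaligned): 45.4 deg
MTDEV (deviation from long axis):  2.8 deg
time to stable alignment:          14 s
```

together with the collision-outcome table: boundary hits shallower than
30° zip along the wall (~99%), steeper hits always catastrophe — the angle
selection that channels the array onto the long axis. Sweeping
eccentricity (`examples/03_eccentricity_sweep.py`) shows mean MTSD falling
monotonically as the cell elongates, and
`examples/05_simulate_render_quantify.py` closes the loop by rasterizing a
simulation and re-quantifying it with the image pipeline (agreement within
a few percent).

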