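# Methods

`mtalign` has two computational cores — a stochastic simulator of
microtubule (MT) self-organization in small 2D cells, and an image-analysis
pipeline that quantifies MT alignment relative to cell shape — plus a
synthetic-data generator that lets each validate the other. This note
records the model, the estimator conventions, the defaults and why they
were chosen, and the known limitations.

## The stochastic model

Each MT is a 1D polymer of tubulin dimers (8.2 nm each) nucleated from one
of `n_seeds` (default 220) seed sites spaced equally along the cell
perimeter, growing along a straight line from an angle drawn uniformly from
the inward half-plane. Dynamic instability is a two-state continuous-time
Markov chain on the dimer count *n*:

* growing `A_n`: add a dimer at rate α (default 1000), or switch to
  shrinking with the loss of a dimer (catastrophe) at rate β′ (default 1);
* shrinking `B_n`: lose a dimer at rate β (default 3500), or add a dimer
  and switch back to growing (rescue) at rate α′ (default 4);
* `B_0`: nothing remains to depolymerize, so the only transition out is a
  rescue at rate α′, which regrows the MT from its seed (by default with a
  freshly drawn inward angle).

Rates are non-dimensional. Anchoring the growth speed
α · (8.2 nm) · R = 0.15 µm s⁻¹ gives the dimensional factor R = 0.01829 s⁻¹
(quoted and applied at four significant figures; `DimensionalRates.R_exact`
keeps full precision), per-second rates rate·R, and seconds(t) = t / R, so
the default horizon t_end = 10 is ≈ 550 s.

The simulation is an exact Gillespie loop over the aggregate rate: the
waiting time is exponential in Σ per-MT rates, one MT is chosen
proportionally, and a single dimer is added or removed. Each added dimer
advances the tip 8.2 nm along its current direction, and the traversed
sub-segment is tested for collisions against every boundary edge and every
other MT's polyline segments (nearest hit wins; hits parallel to within
numerical tolerance are ignored).

### Collision rules

A collision is characterized by the acute axial angle θ ∈ (0°, 90°] between
the tip direction and the obstacle's tangent. Under the full
`angle_dependent` rule set with critical angle θ_c = 30° and crossing
catastrophe probability p_cat = 0.01:

* θ < θ_c: catastrophe with probability (θ/θ_c)·p_cat, otherwise **zip** —
  the tip bends parallel to the obstacle (sign chosen to minimize turning)
  and a new polyline segment begins; collinear overlap of zipped MTs is
  what constitutes a bundle, and bundles render brighter in proportion to
  occupancy;
* θ ≥ θ_c against another MT: catastrophe with probability p_cat,
  otherwise **cross** (pass through);
* θ ≥ θ_c against the cell boundary: certain catastrophe. θ exactly equal
  to θ_c takes the steep branch.

Three reduced rule sets reproduce the model-development sequence:
`stabilize_no_cross` (MT–MT catastrophe, boundary stabilization — arrays
orient along the **short** axis), `cross_stabilize` (crossover plus
boundary stabilization — a static mesh), and `cross_boundary_cat`
(crossover plus boundary catastrophe — long-axis alignment but no
bundles). "Stabilize" pauses the tip; the paused MT remains subject to
spontaneous catastrophe at β′.

### Cell geometry

`build_cell_domain(width, e)` supports three mappings from eccentricity to
a convex polygon with the long axis on x:

* `rectangle` (the geometric default): length = width/√(1−e²), the aspect
  ratio of the moment-equivalent ellipse;
* `area_matched` (the default for simulation protocols): length =
  0.632·width/(1−e²). This law was recovered from the cell areas the
  reference simulations report (area·(1−e²) is constant across their
  eccentricity range, for both the 492 nm and 984 nm widths) and reproduces
  all four printed area endpoints to ~2%. At high eccentricity these cells
  are about twice as elongated as the moment-ellipse rectangle, which is
  what pushes the simulated MTSD into the observed high-alignment regime;
* `trapezoid`: an isosceles trapezoid with the same height and mean length
  (taper configurable), for shape-sensitivity checks.

### Alignment readout

Every `sample_dt` (default 0.01) the simulator bins all polymer into a
length-weighted axial direction histogram (180 one-degree bins). MTSD is
the σ of an axial von Mises moment fit (below); the reported final MTSD
fits the histogram averaged over the last `avg_window` (default 2.5, i.e.
250 samples). Convergence detection runs on the trailing
`avg_window`-averaged series — the same averaging convention as the final
estimate — because the instantaneous histogram of ~10²–10³ short filaments
is too noisy an estimator of σ for a ±10% band to be meaningful. The raw
per-sample series is retained on `SimResult.mtsd_series`. The convergence
time is the first time after which the averaged series stays within ±10%
(relative) of its convergence value, defined as its mean over the final
window; an empty system reports the unaligned sentinel MTSD = 90°.

## Axial circular statistics

Filament directions are axial (period 180°). All fits use the double-angle
transform: angles are doubled, the weighted circular resultant (C, S, R̄)
is computed over bin centres, μ = ½·atan2(S, C) mapped to [0°, 180°), and
σ = min(90°, ½·√(−2 ln R̄) in degrees). κ inverts A(κ) = I₁/I₀ = R̄
(Fisher's approximations refined by root-finding). This closed-form moment
fit is deterministic, and σ exactly inverts a wrapped-normal generator
(R̄ = exp(−2σ²) with σ in radians), which is what makes generating spreads
of 22/30/40° recoverable in validation. R̄ ≈ 0 (uniform or empty input)
reports σ = 90° with μ undefined.

The shared-line comparison between MTSD–eccentricity datasets is the
extra-sum-of-squares F test (one pooled line versus per-dataset lines);
the MTDEV–eccentricity relation is summarized by a least-squares one-phase
exponential decay y = (y₀ − plateau)·exp(−k·x) + plateau.

## Image pipeline

Z-stacks are maximum-projected; intensities are contrast-stretched with
0.5% clipped at each extreme; gradients come from separable 5×5 Sobel
operators (smoothing [1, 4, 6, 4, 1] ⊗ derivative [−1, −2, 0, 2, 1] — the
5×5 "Sobel" is not unique in the literature, so this form is declared
canonical here), giving per-pixel magnitude M and direction D. Per cell
(integer label mask): the mask is eroded by the 2 px kernel half-width so
mask edges cannot inject spurious directions; pixels with M below 22% of
the cell's maximum are discarded; surviving directions are rotated by 90°
(a gradient is perpendicular to its filament), binned at 4°, weighted by M
and normalized. The axial von Mises fit gives the MT main direction and
MTSD; MTDEV is the acute angle to the cell's long axis from the
moment-ellipse fit of the mask (second central moments of pixel centres;
orientation in degrees counter-clockwise from x with y up). Cells with
fewer than 50 surviving pixels are flagged and excluded from summaries.
Whole-field mode runs the identical pipeline with the frame (or a supplied
region) as the single mask, thresholding against the field maximum.
Time-lapse stacks of growing plus-end trajectories are quantified by
applying the same per-frame pipeline; no tracking.

The independent cross-check is a Hann-windowed 2D power spectrum binned by
spectral orientation rotated 90° onto real-space direction, restricted to
the inscribed frequency disc (the spectrum's corners would over-weight
diagonals) with the lowest radii excluded as window leakage.

## Synthetic data

`generate_line_image` draws `n_lines` (default 100) anchors uniformly
inside an ellipse of chosen eccentricity and renders anti-aliased straight
filaments whose axial angles are Normal(mean, σ) wrapped to 180°, plus a
label mask and a JSON-serializable `LineSet` ground truth;
`ground_truth_mtsd` is the length-weighted axial fit of the true angles.
Default line length is fixed (the minor-axis diameter, clipped to the
cell) rather than full chords: chord length depends on angle in an
elongated cell, which would length-weight the angular statistics several
degrees below the generating σ at high eccentricity. Even with fixed
lengths, boundary clipping compresses the realized spread slightly (the
ground truth reports the realized value, e.g. ~38° for nominal 40° at
e = 0.7), and the pipeline tracks the realized ground truth closely.

`render_simulation` rasterizes final polylines additively (bundle
occupancy → brightness) with the domain polygon as the mask; because the
render is a single time point, its reference statistic is the
final-snapshot MTSD, not the last-window average. `generate_cell_field`
tiles cells with a controllable dispersion of long-axis orientations to
emulate coherent versus incoherent epithelial sheets for the cell-by-cell
versus whole-field comparison.

What the generator does **not** emulate: microscope point-spread blur,
curved or crossing-suppressed filaments, intensity variation along a
filament, or structured background. Passing recovery tests therefore
demonstrate correctness of the estimator chain on idealized filament
images, not robustness to real acquisition artifacts.

## Numerical choices

* Collision detection accepts hits at s ≥ 0 along the step: boundary hits
  additionally require outward motion (d·n̂_out > 0), which both contains a
  tip regrowing from a zip crease exactly on the wall and leaves a freshly
  nucleated seed unaffected by its own wall.
* A crossing tip overshoots the crossed obstacle by 10⁻⁶ nm so it is not
  re-detected; the boundary wins any tie within twice that distance, so a
  crossing resolved against a wall-hugging bundle segment can never tunnel
  through the wall.
* Near-parallel intersections (|cross product| ≤ 10⁻¹⁰ per unit length)
  are ignored; collinear bundle members are therefore transparent to each
  other and an incident MT meets a bundle as one obstacle.
* Zip ties at exactly 90° break toward positive orientation; per-MT
  polylines are capped at 384 segments and a 64-iteration guard bounds
  zig-zag resolution within one dimer step (either limit triggers a
  catastrophe; both are unreachable in ordinary runs).
* The RNG is xorshift128+ with per-run state seeded via
  `numpy.random.SeedSequence`; identical seeds give bit-identical event
  logs, and sweep runs derive per-run seeds deterministically.

## Design decisions

* **B₀ rescue-wait renucleation (default).** A fully depolymerized MT
  waits in `B_0` for a rescue (mean dwell 1/α′ = 0.25 time units ≈ 13.7 s)
  before regrowing — the literal two-state chain. This dwell is
  load-bearing: with instant renucleation (available as
  `renucleation="instant"`) the constantly re-injected random-angle
  transients outweigh the aligned bundles and the steady-state MTSD rises
  by ~20°.
* **Collision catastrophes are ordinary catastrophes** (rescuable); a
  variant in which they collapse the MT completely is available
  (`collapse_on_collision`) but off by default.
* **R is applied at 4 significant figures** in the dimensional table, the
  precision at which the factor is conventionally quoted; exact R is also
  returned.
* **Angle convention** everywhere: degrees counter-clockwise from the
  x axis with y up, axial quantities modulo 180°, comparisons by acute
  axial difference.

## Limitations

* At low eccentricity (e ≈ 0.7) the simulated steady state is only weakly
  ordered (MTSD ≈ 65–70°), higher than the reference regime (≈ 45°); the
  residual gap presumably reflects unpublished implementation details of
  the original model. A practical consequence is that e = 0.7 convergence
  times are heavy-tailed (median ≈ 225 s, occasional runs > 440 s).
* The two cell widths (492 and 984 nm, same 220 seeds) show a small but
  systematic steady-state MTSD offset of ~4°, so the shared-line F test on
  two-width sweeps rejects more often than not even though the sweep
  curves are visually coincident; the relation is close to, but not
  exactly, size-invariant in this implementation.
* The model omits MT severing, motor transport, tubulin-pool depletion and
  any 3D structure; zipped MTs never unzip, and bundle members interact
  with obstacles individually.
* Simulation protocol sizes used throughout the tests and examples (220
  seeds, t_end = 10, three runs per condition, 256 px validation images)
  are the reference conditions of the study design; sweep helpers accept
  smaller values for exploratory work.
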