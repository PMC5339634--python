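# Methods

## Model and detection algorithm

A sideways parabola is stored in general form `x = A·y² + B·y + C` (column as
a function of row; `A` in 1/pixels, `B` dimensionless, `C` in pixels). The
vertically opening family is handled by transposing the image before detection
and transposing results back, so a single code path serves both orientations.
Three pixels with pairwise-distinct rows determine the coefficients in closed
form (the unique interpolating quadratic); the closed form is checked against
a generic Vandermonde solve in the tests. `|A| < 1e-12` is treated as a line
and rejected — lines are the aperture→∞ limit of the family and must not
masquerade as detections. Derived quantities are the vertex
`(C − B²/(4A), −B/(2A))` and the aperture `4p = 1/A`, which satisfies
`4p·A = 1` identically.

Candidates are scored against the binary edge image `f_binary` by rasterizing
the curve into a virtual-shape image `I_VS` (one pixel per row, rounding
half-away-from-zero) and summing the Hadamard product `f_binary ⊙ I_VS`: the
fitness is the count of edge pixels the curve passes through, at most one per
row. The implementation evaluates this row-wise without materializing `I_VS`;
equivalence with the dense product is property-tested. An optional
`thickness` parameter dilates `I_VS` with a disk, for matching against thick
edge maps.

The optimizer is a univariate marginal distribution algorithm over bit
strings. The `N` foreground pixels are indexed in row-major scan order;
an individual is three indices, each encoded MSB-first in `L = ⌈log₂ N⌉`
bits and concatenated (3·L bits). Per generation: sample the population from
the per-bit Bernoulli marginals, evaluate, select the top `⌈0.6·n⌉` by
fitness (ties broken by population position), and re-estimate the marginals
as the selected set's per-bit frequencies. Defaults are 10 individuals,
selection rate 0.6 and at most 30 generations. Further numerical choices:

- **Marginal clamp.** Estimated probabilities are clamped to
  `[1/(3L), 1 − 1/(3L)]`, keeping every bit mutable (roughly one expected
  bit flip per individual) and preventing irreversible lock-in.
- **Initialization.** All marginals start at 0.5 (uniform over encodings).
- **Invalid genes.** A sampled gene decoding to an index ≥ N is re-drawn from
  the same marginals up to 16 times, then replaced by a uniform valid index;
  a modulo mapping would bias toward low scan-order indices.
- **Degenerate candidates.** Repeated indices, out-of-range indices and
  geometrically degenerate triplets score fitness 0 rather than raising, so
  the evolutionary loop is total.
- **Stopping.** The loop ends at the generation cap, or early when every
  marginal sits at its clamp bound or the population fitness spread is zero.
- **No elitism.** The global best is tracked separately and reported at the
  end but never re-injected into the population.
- **Reported iterations.** `best_generation` is the generation at which the
  global best last improved ("iterations to the best result");
  `generations` counts all generations executed. Both are reported because
  published iteration counts are smaller than the generation cap, which
  matches the last-improvement reading.

Detection is deterministic given a seed; wall-clock time is logged for
information only and is never used as evidence (it is hardware-dependent).

## Baselines

The Hough baseline votes in the vertex parameterization
`(y − y0)² = 4a(x − x0)`: for each edge pixel and each `(a, y0)` cell the
vertex abscissa `x0` is solved and binned to the nearest axis value (within
half a local grid gap); the accumulator peak (lowest linear index on ties) is
converted back to general form. Grid resolutions are configuration — the
published experiments do not state them — with a coarse frame-spanning
default.

RANSAC draws three distinct edge pixels per iteration (5000 by default,
matching the published benchmark configuration), fits the same three-point
solver, counts inliers by per-row horizontal residual (|x − x(y)| ≤ 2 px by
default, suiting edges dilated by a radius-3 disk), then refits the best
model on its inliers via the 3×3 quadratic normal equations assembled
in-repo. The reported inlier count is recounted against the refit model, and
the sample model is kept if the refit is worse. Per-row horizontal residual,
rather than geometric point-to-curve distance, matches the functional form
the fitness uses.

## Synthetic scenes

`generate_scene` renders one parabola among `n_lines` straight segments
(integer line stepping) and `n_circles` circle perimeters (midpoint
rasterization) in a 512×512 frame by default. Coefficients are drawn by
sampling `|A|` from 0.004–0.02 with random sign and the vertex uniformly from
the central 60 % of the frame; draws are repeated (≤100) until the curve's
in-frame rasterization has 300–500 pixels. Two constraints make the ground
truth well-posed, i.e. guarantee that at zero noise no member of the searched
family out-scores the planted curve (the detectors' fitness upper bound
equals the planted pixel count):

1. **Distractor lines are no steeper than 45°.** A near-vertical line is
   itself approximately a sideways parabola (the `A → 0` limit), and a
   512-row line can collect more matched pixels than a 300–500-pixel planted
   curve; bounding the slope caps any line's best quadratic match well below
   the planted count.
2. **The planted curve sits at the prominent end of the admissible 100–500
   pixel range**, so it dominates circle arcs (a circle's lateral arc is
   parabola-like over roughly `(4r³)^{1/4}` rows, ~100 pixels at the default
   radii).

Salt-and-pepper noise on a binary image is implemented as exact-count site
resampling: `round(f·H·W)` distinct sites are chosen without replacement and
each is set to 1 or 0 with probability ½ (the grayscale extremes coincide
with the binary values, so impulse noise reduces to this). Skeletonization
is Zhang–Suen thinning via scikit-image. The noise battery is 10 base scenes
× integer levels 0–25 %, 260 images, truths carried over.

What the generator emulates: binary edge maps containing one dominant
parabolic contour among parametric clutter, with impulse noise. What it does
not emulate: thick (stroke- or dilation-width) curves, textured backgrounds,
vessel trees, contrast variation, or correlated noise — passing tests here
demonstrate correctness of the algorithmic pipeline under the stated
protocol, not clinical performance on retinal or footprint photographs.

## Preprocessing chain

Grayscale photographs are conditioned by a 3×3 mean filter (replicate
padding; the published kernel), Canny edge detection (hysteresis thresholds
default to Otsu's threshold of the Sobel gradient magnitude and half of it —
the published work states none), and morphological dilation with a disk of
radius 3 (membership: center distance ≤ radius), yielding the edge image the
detectors consume. Footprint images are cut into three horizontal bands of
near-equal height (remainder rows to the top band; fingers assumed at the
top, `flip` otherwise); the middle band is the plantar-arch region and the
bottom band the heel. Each band is transposed so the canonical sideways
solver applies, and results are mapped back to full-image coordinates as
vertically opening parabolas. Vertical body edges become constant-row point
sets after transposition and are degenerate for the solver, which usefully
suppresses them as attractors.

## Fit metrics

The RMSD between a reference and a detected curve is computed analytically on
the functional forms over all image rows; the matched-point cardinality is
the number of rows on which the two rounded columns coincide. The normalized
RMSD divides the raw value by that cardinality (the published convention,
prioritizing fits with many matched points); the raw value is always reported
alongside, and an in-frame-only comparison mode is available. The benchmark
driver derives every per-run seed deterministically from one master seed, so
result tables are reproducible bit for bit (wall-clock columns aside).

## Evaluation protocol sizes and known limitations

The acceptance script and the end-to-end tests use 512×512 scenes, 30 runs
per experiment, and a noise sweep of 0–35 % in 5-point steps — a single
detection is ~300 fitness evaluations, so the full protocol completes in
seconds.

Two protocol-level limitations are worth stating plainly, because they bound
what the evaluation can show:

- **Exact raster recovery is not generally attainable.** The detector only
  ever fits curves through *rounded* pixel coordinates. For wide parabolas
  (several hundred rows in frame) no triplet of raster pixels reproduces the
  planted rasterization exactly, and the best achievable Hadamard fitness is
  a few pixels below the planted count. Recovery should therefore be judged
  by overlap fractions or by RMSD (sub-pixel in practice; the clean-scene
  normalized RMSD here is ~1e-4, well inside the published 0.0026), not by
  bit-exact raster equality.
- **Impulse-noise robustness is regime-dependent.** With thin one-pixel
  curves in a 512×512 frame, 5 % site noise already multiplies the
  foreground count several-fold, and an all-on-curve triplet becomes too rare
  for a 300-evaluation budget to find reliably; majorities of runs stop
  recovering the planted curve at the first noise step. The published
  robustness claim (detection up to ~30 % noise) is tied to thick-stroke
  images, where the curve holds a far larger share of the foreground and
  near-miss candidates still score: its own noisy-fit tables print RMS
  deviations of 9–14 px. The sweep here reports the measured breakdown point
  under the thin-raster protocol rather than reproducing that claim.
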