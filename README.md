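# paradetect

Fast parabola detection in binary edge images with an estimation-of-distribution
optimizer, plus Hough-transform and RANSAC baselines.

Parabolic contours are everywhere in medical image analysis: the major temporal
arcade of retinal vessels in fundus photographs, and the plantar arch and heel
outline in footprint images used for orthopedic assessment, are both well
approximated by parabolas. Classical Hough voting over the three parameters of
a parabola is accurate but slow, because every edge pixel votes across a 3-D
accumulator. `paradetect` instead searches directly over *triplets of edge
pixels*: any three pixels with distinct rows determine a unique sideways
parabola

    x = A·y² + B·y + C,

with vertex at `y = −B/(2A)`, `x = C − B²/(4A)` and aperture (latus rectum)
`4p = 1/A`. A candidate triplet is scored by rasterizing its parabola into a
virtual-shape image and taking the Hadamard (elementwise) product with the
binary edge image — the fitness is simply the number of edge pixels the
candidate curve passes through. A univariate marginal distribution algorithm
(UMDA) drives the search: each individual is the three pixel indices
concatenated as a bit string (`L = ⌈log₂ N⌉` bits per index for `N` edge
pixels), the best 60 % of each 10-individual generation is selected, per-bit
marginal frequencies are re-estimated, and the next generation is sampled from
them, for at most 30 generations — a few hundred fitness evaluations per
detection instead of millions of accumulator votes.

The package provides:

- `geometry` — closed-form three-point parabola fitting, vertex/aperture,
  evaluation and rasterization;
- `umda` — pixel indexing, binary encoding, Hadamard fitness and the
  detection loop;
- `baselines` — a 3-parameter parabola Hough transform and RANSAC with a
  least-squares refit, for comparison;
- `synthetic` — ground-truthed scene generation (one parabola among line and
  circle distractors), exact-fraction salt-and-pepper noise, skeletonization,
  and the 260-image noise battery (10 base scenes × 0–25 % noise);
- `preprocess` — the mean-filter → Canny → disk-dilation chain for grayscale
  photographs, and footprint sectioning with per-band arch/heel detection;
- `metrics` — per-row RMSD with cardinality normalization, matched-point
  counts and benchmark orchestration;
- a `paradetect` command line with `detect`, `simulate` and `benchmark`
  subcommands.

## Worked example

```python
import numpy as np
from paradetect import generate_scene, run, UMDAParams, rmsd, vertex_and_aperture

scene = generate_scene(seed=11)          # 512x512, one parabola, 3 lines, 2 circles
result = run(scene.image, UMDAParams(seed=0))
p = result.parabola
v, four_p = vertex_and_aperture(p)
rep = rmsd(scene.truth, p, 512)
print(result.fitness, scene.truth_pixel_count, result.best_generation)
print(f"A={p.A:.6f} vertex=({v.x:.1f}, {v.y:.1f}) 4p={four_p:.1f}")
print(f"RMSD={rep.rmsd_raw:.4f} px, matched={rep.matched_points}, "
      f"normalized={rep.rmsd_normalized:.6f}")
```

prints

```
280 378 28
A=0.007279 vertex=(250.6, 272.6) 4p=137.4
RMSD=0.2787 px, matched=392, normalized=0.000711
```

The detector matched 280 of the 378 planted curve pixels, last improved its
best solution at generation 28, and its curve deviates from the planted one by
0.28 px RMS over all 512 rows; the planted parabola had `A=0.007272` and
vertex `(251.0, 272.5)`, so vertex and aperture are recovered to sub-pixel
accuracy. The normalized RMSD divides the raw deviation by the number of
matched rows (392), following the cardinality convention.

The same detection is available from the shell:

```sh
paradetect simulate --out-dir scenes --seed 11
paradetect detect scenes/scene_0000.png --seed 0 --overlay overlay.png
```

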