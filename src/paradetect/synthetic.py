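"""Ground-truthed synthetic scenes for benchmarking the detectors.

A scene is a binary edge image containing exactly one parabola drawn from its
general form, among randomly placed straight-line and circle distractors.
Impulse ("salt and pepper") noise can be added at an exact per-image fraction,
and scenes can be thinned to one-pixel skeletons.  The noise battery mirrors
the evaluation protocol of ten base scenes swept over integer noise levels
0..25 %, i.e. 260 images in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from skimage.draw import circle_perimeter, line as draw_line
from skimage.morphology import skeletonize as _skimage_skeletonize

from .errors import RetryExhaustedError
from .geometry import Orientation, Parabola, rasterize
from .umda import EdgeImage, index_pixels


# ---------------------------------------------------------------------------
# Shape descriptors


@dataclass(frozen=True)
class LineSegment:
    """Distractor line, stored by its integer endpoints (x = col, y = row)."""

    x0: int
    y0: int
    x1: int
    y1: int

    def rasterize(self, height: int, width: int) -> np.ndarray:
        img = np.zeros((height, width), dtype=bool)
        rr, cc = draw_line(self.y0, self.x0, self.y1, self.x1)
        ok = (rr >= 0) & (rr < height) & (cc >= 0) & (cc < width)
        img[rr[ok], cc[ok]] = True
        return img


@dataclass(frozen=True)
class CircleShape:
    """Distractor circle, stored by center and radius (midpoint rasterization)."""

    cx: int
    cy: int
    radius: int

    def rasterize(self, height: int, width: int) -> np.ndarray:
        img = np.zeros((height, width), dtype=bool)
        rr, cc = circle_perimeter(self.cy, self.cx, self.radius,
                                  shape=(height, width))
        img[rr, cc] = True
        return img


Distractor = Union[LineSegment, CircleShape]


@dataclass
class SyntheticScene:
    """A rendered edge image plus the exact parameters used to draw it."""

    image: EdgeImage
    truth: Parabola
    distractors: List[Distractor] = field(default_factory=list)
    noise_fraction: float = 0.0
    seed: Optional[int] = None

    @property
    def truth_pixel_count(self) -> int:
        """In-frame pixel count of the planted curve's rasterization."""
        return int(rasterize(self.truth, self.image.height, self.image.width).sum())


# ---------------------------------------------------------------------------
# Scene generation

#: Default magnitude range for the quadratic coefficient A (1/pixels).  With a
#: 512-pixel frame these apertures give planted curves spanning roughly
#: 100-500 in-frame pixels once the vertex is placed in the central region;
#: the default pixel-count target keeps draws at the prominent end of that
#: range so the planted curve dominates every distractor (see generate_scene).
DEFAULT_A_RANGE = (0.004, 0.02)


def _draw_parabola(height: int, width: int, rng: np.random.Generator,
                   coeff_ranges: Optional[dict]) -> Parabola:
    """Draw random general-form coefficients.

    When explicit ``coeff_ranges`` (keys "A", "B", "C" mapping to (lo, hi))
    are given, the coefficients are sampled uniformly from them.  Otherwise
    ``A`` is drawn from :data:`DEFAULT_A_RANGE` with a random sign and the
    vertex uniformly from the central 60 % of the frame, from which B and C
    follow.
    """
    if coeff_ranges is not None:
        A = rng.uniform(*coeff_ranges["A"])
        B = rng.uniform(*coeff_ranges["B"])
        C = rng.uniform(*coeff_ranges["C"])
        return Parabola(A, B, C, Orientation.X_OF_Y)
    A = rng.uniform(*DEFAULT_A_RANGE) * rng.choice([-1.0, 1.0])
    y_v = rng.uniform(0.2 * height, 0.8 * height)
    x_v = rng.uniform(0.2 * width, 0.8 * width)
    # x = A (y - y_v)^2 + x_v  expanded to the general form
    return Parabola(A, -2.0 * A * y_v, A * y_v * y_v + x_v, Orientation.X_OF_Y)


def generate_scene(height: int = 512, width: int = 512, n_lines: int = 3,
                   n_circles: int = 2, coeff_ranges: Optional[dict] = None,
                   rng: Optional[np.random.Generator] = None,
                   seed: Optional[int] = None,
                   target_pixels: Optional[Tuple[int, int]] = None) -> SyntheticScene:
    """Render one parabola among line and circle distractors.

    The scene is constructed so the planted curve is the unambiguous ground
    truth: at zero noise no parabola in the searched family can out-score it.
    A straight line steeper than 45 degrees is itself approximately a
    sideways parabola (the zero-curvature limit of the general form), so
    distractor lines are redrawn until they are no steeper than 45 degrees,
    and the planted curve is drawn at the prominent end of the admissible
    100-500 pixel range (``target_pixels``).  The parabola is redrawn (at
    most 100 times) until its in-frame rasterization has a pixel count within
    ``target_pixels``; if no draw reaches even 10 pixels a
    :class:`RetryExhaustedError` is raised.  Deterministic given a seed or
    generator.
    """
    if height <= 0 or width <= 0:
        raise ValueError("scene dimensions must be positive")
    if target_pixels is None:
        # prominent end of the admissible range, clipped for small frames
        target_pixels = (min(300, max(10, int(0.6 * height))), min(500, height))
    if rng is None:
        rng = np.random.default_rng(seed)

    grid = np.zeros((height, width), dtype=bool)
    distractors: List[Distractor] = []
    for _ in range(n_lines):
        for _attempt in range(100):
            seg = LineSegment(
                x0=int(rng.integers(0, width)), y0=int(rng.integers(0, height)),
                x1=int(rng.integers(0, width)), y1=int(rng.integers(0, height)),
            )
            if abs(seg.y1 - seg.y0) <= abs(seg.x1 - seg.x0):
                break
        distractors.append(seg)
        grid |= seg.rasterize(height, width)
    max_r = max(5, min(height, width) // 4)
    for _ in range(n_circles):
        circ = CircleShape(
            cx=int(rng.integers(0, width)), cy=int(rng.integers(0, height)),
            radius=int(rng.integers(5, max_r + 1)),
        )
        distractors.append(circ)
        grid |= circ.rasterize(height, width)

    truth = None
    fallback = None
    for _ in range(100):
        cand = _draw_parabola(height, width, rng, coeff_ranges)
        count = int(rasterize(cand, height, width).sum())
        if target_pixels[0] <= count <= target_pixels[1]:
            truth = cand
            break
        if count >= 10 and fallback is None:
            fallback = cand
    if truth is None:
        truth = fallback
    if truth is None:
        raise RetryExhaustedError(
            "could not draw a parabola with at least 10 in-frame pixels"
        )
    grid |= rasterize(truth, height, width)

    return SyntheticScene(image=index_pixels(grid), truth=truth,
                          distractors=distractors, noise_fraction=0.0, seed=seed)


# ---------------------------------------------------------------------------
# Noise and thinning


def add_salt_pepper(img: EdgeImage, fraction: float,
                    rng: Optional[np.random.Generator] = None,
                    seed: Optional[int] = None) -> EdgeImage:
    """Impulse noise at an exact site fraction.

    ``round(fraction * height * width)`` distinct pixel sites are chosen
    uniformly without replacement; each chosen site is set to 1 (salt) with
    probability 1/2 and to 0 (pepper) otherwise.  On a binary edge image the
    grayscale extremes coincide with the two binary values, so impulse noise
    reduces to this site resampling.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("noise fraction must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    flat = img.grid.copy().reshape(-1)
    n_sites = int(round(fraction * flat.size))
    if n_sites > 0:
        sites = rng.choice(flat.size, size=n_sites, replace=False)
        flat[sites] = rng.integers(0, 2, size=n_sites).astype(bool)
    return index_pixels(flat.reshape(img.grid.shape), min_pixels=0)


def skeletonize(img: EdgeImage) -> EdgeImage:
    """Morphologically thin the foreground to one-pixel-wide medial curves."""
    return index_pixels(_skimage_skeletonize(img.grid), min_pixels=0)


# ---------------------------------------------------------------------------
# Noise battery


def build_noise_battery(n_base: int = 10,
                        noise_levels: Sequence[int] = tuple(range(0, 26)),
                        rng: Optional[np.random.Generator] = None,
                        seed: Optional[int] = None,
                        **scene_kwargs) -> List[SyntheticScene]:
    """Base scenes swept over integer noise percentages.

    Defaults reproduce the evaluation battery: 10 base scenes, each corrupted
    at every integer level 0..25 %, for 260 images in total.  The planted
    truth of each base scene is carried over to all of its noisy variants.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    scenes: List[SyntheticScene] = []
    for b in range(n_base):
        base = generate_scene(rng=rng, **scene_kwargs)
        for level in noise_levels:
            frac = level / 100.0
            noisy = base.image if level == 0 else add_salt_pepper(base.image, frac, rng)
            scenes.append(SyntheticScene(
                image=noisy, truth=base.truth,
                distractors=list(base.distractors),
                noise_fraction=frac, seed=seed,
            ))
    return scenes
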