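"""Comparison detectors: a 3-parameter parabola Hough transform and RANSAC.

Both baselines work in the vertex parameterization ``(y - y0)^2 = 4a (x - x0)``
of a sideways-opening parabola, equivalent to the general form used by the
evolutionary detector via ``A = 1/(4a)``, ``B = -y0/(2a)``,
``C = y0^2/(4a) + x0``.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .errors import DegenerateTripletError, EmptyImageError
from .geometry import Orientation, Parabola, evaluate, fit_three_points
from .umda import DetectionResult, EdgeImage


def vertex_form_to_general(x0: float, y0: float, a: float) -> Parabola:
    """Convert ``(y - y0)^2 = 4a (x - x0)`` to ``x = A y^2 + B y + C``."""
    if a == 0:
        raise ValueError("aperture parameter a must be nonzero")
    A = 1.0 / (4.0 * a)
    return Parabola(A, -2.0 * A * y0, A * y0 * y0 + x0, Orientation.X_OF_Y)


# ---------------------------------------------------------------------------
# Hough transform


@dataclass
class HoughGrid:
    """Discretized ``(x0, y0, a)`` parameter space with a 3D vote accumulator."""

    x0_values: np.ndarray
    y0_values: np.ndarray
    a_values: np.ndarray
    accumulator: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.x0_values = np.asarray(self.x0_values, dtype=float)
        self.y0_values = np.asarray(self.y0_values, dtype=float)
        self.a_values = np.asarray(self.a_values, dtype=float)
        if self.x0_values.size == 0 or self.y0_values.size == 0 or self.a_values.size == 0:
            raise ValueError("all parameter axes must be non-empty")
        if np.any(self.a_values == 0):
            raise ValueError("aperture axis must exclude a = 0")
        if self.accumulator is None:
            self.accumulator = np.zeros(
                (self.x0_values.size, self.y0_values.size, self.a_values.size),
                dtype=np.int64,
            )


def default_grid(height: int, width: int, n_x0: int = 32, n_y0: int = 32,
                 a_values: Optional[np.ndarray] = None) -> HoughGrid:
    """A coarse default grid spanning the frame with two-sided apertures."""
    if a_values is None:
        mags = np.array([5.0, 10.0, 20.0, 40.0, 80.0])
        a_values = np.concatenate([-mags[::-1], mags])
    return HoughGrid(
        x0_values=np.linspace(0, width - 1, n_x0),
        y0_values=np.linspace(0, height - 1, n_y0),
        a_values=np.asarray(a_values, dtype=float),
    )


def _nearest_bin(values: np.ndarray, axis: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Nearest-bin index on a sorted axis; valid only within half a local gap."""
    idx = np.searchsorted(axis, values)
    idx = np.clip(idx, 1, axis.size - 1) if axis.size > 1 else np.zeros_like(idx)
    if axis.size > 1:
        left = axis[idx - 1]
        right = axis[idx]
        idx = np.where(np.abs(values - left) <= np.abs(right - values), idx - 1, idx)
        gaps = np.diff(axis)
        half = np.empty(axis.size)
        half[0] = gaps[0] / 2
        half[-1] = gaps[-1] / 2
        if axis.size > 2:
            half[1:-1] = np.maximum(gaps[:-1], gaps[1:]) / 2
        ok = np.abs(values - axis[idx]) <= half[idx] + 1e-9
    else:
        ok = np.isfinite(values)
    return idx, ok


def hough_detect(img: EdgeImage, grid: HoughGrid) -> Tuple[Parabola, HoughGrid]:
    """Vote over ``(x0, y0, a)`` and return the accumulator-peak parabola.

    For every foreground pixel ``(x, y)`` and every ``(a, y0)`` cell the
    vertex abscissa ``x0 = x - (y - y0)^2 / (4a)`` is solved and binned; the
    peak (lowest linear index on ties) is converted to general form.
    """
    acc = grid.accumulator
    acc[:] = 0
    xs = img.foreground_x.astype(float)
    ys = img.foreground_y.astype(float)
    for ia, a in enumerate(grid.a_values):
        for iy0, y0 in enumerate(grid.y0_values):
            x0 = xs - (ys - y0) ** 2 / (4.0 * a)
            ix0, ok = _nearest_bin(x0, grid.x0_values)
            np.add.at(acc[:, iy0, ia], ix0[ok], 1)
    flat_peak = int(np.argmax(acc))  # argmax returns the first (lowest) index on ties
    ix0, iy0, ia = np.unravel_index(flat_peak, acc.shape)
    parab = vertex_form_to_general(
        grid.x0_values[ix0], grid.y0_values[iy0], grid.a_values[ia]
    )
    return parab, grid


# ---------------------------------------------------------------------------
# RANSAC


@dataclass
class RansacParams:
    """RANSAC settings.

    The default 5000 iterations match the benchmark configuration of the
    comparison tables; the 2-pixel inlier tolerance suits the 3-pixel-thick
    dilated edges produced by preprocessing and is fully configurable.
    """

    iterations: int = 5000
    inlier_tolerance: float = 2.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.inlier_tolerance <= 0:
            raise ValueError("inlier tolerance must be positive")


def count_inliers(img: EdgeImage, p: Parabola, tolerance: float) -> int:
    """Foreground pixels with per-row horizontal residual within tolerance."""
    resid = np.abs(img.foreground_x - evaluate(p, img.foreground_y.astype(float)))
    return int(np.sum(resid <= tolerance))


def _least_squares_refit(ys: np.ndarray, xs: np.ndarray) -> Parabola:
    """Quadratic least squares via the 3x3 normal equations assembled in-place."""
    y = ys.astype(float)
    x = xs.astype(float)
    # moments of y up to order 4 and cross moments with x
    S = [np.sum(y ** k) for k in range(5)]
    T = [np.sum(x * y ** k) for k in range(3)]
    M = np.array([[S[4], S[3], S[2]],
                  [S[3], S[2], S[1]],
                  [S[2], S[1], S[0]]])
    rhs = np.array([T[2], T[1], T[0]])
    coef = np.linalg.solve(M, rhs)
    return Parabola(coef[0], coef[1], coef[2], Orientation.X_OF_Y)


def ransac_detect(img: EdgeImage, params: RansacParams = RansacParams(),
                  rng: Optional[np.random.Generator] = None) -> DetectionResult:
    """Random-sample-consensus parabola fit with a final least-squares refit.

    Repeatedly fits the three-point solver to random distinct foreground
    pixels, scores by inlier count (per-row horizontal residual within
    tolerance), refits the best model on its inliers, and reports the inlier
    count recounted against the refit model.  Deterministic for a fixed seed.
    """
    if img.N < 3:
        raise EmptyImageError("need at least 3 foreground pixels")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    start = time.perf_counter()

    best_model: Optional[Parabola] = None
    best_count = -1
    best_iter = 0
    for it in range(1, params.iterations + 1):
        i, j, k = rng.choice(img.N, size=3, replace=False)
        try:
            model = fit_three_points(img.point(i), img.point(j), img.point(k))
        except DegenerateTripletError:
            continue
        n_in = count_inliers(img, model, params.inlier_tolerance)
        if n_in > best_count:
            best_count = n_in
            best_model = model
            best_iter = it

    if best_model is None:
        return DetectionResult(parabola=None, fitness=0,
                               generations=params.iterations, best_generation=0,
                               evaluations=params.iterations,
                               elapsed=time.perf_counter() - start)

    resid = np.abs(
        img.foreground_x - evaluate(best_model, img.foreground_y.astype(float))
    )
    mask = resid <= params.inlier_tolerance
    try:
        refit = _least_squares_refit(img.foreground_y[mask], img.foreground_x[mask])
    except (np.linalg.LinAlgError, DegenerateTripletError):
        refit = best_model
    final_count = count_inliers(img, refit, params.inlier_tolerance)
    if final_count < best_count:  # keep the better of sample model and refit
        refit, final_count = best_model, best_count
    return DetectionResult(
        parabola=refit,
        fitness=final_count,
        generations=params.iterations,
        best_generation=best_iter,
        evaluations=params.iterations,
        elapsed=time.perf_counter() - start,
    )
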