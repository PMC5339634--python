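"""Closed-form parabola algebra on pixel grids.

A parabola is stored in its general form ``A t**2 + B t + C = s`` where the
quadratic argument ``t`` runs along one image axis and ``s`` along the other.
The canonical orientation is ``X_OF_Y`` (a sideways parabola, column as a
function of row); the transposed orientation ``Y_OF_X`` is obtained by
transposing the image before detection and transposing results back, so a
single code path covers both opening directions.

Coordinates are 0-based with ``x`` = column and ``y`` = row, origin at the
top-left corner.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .errors import DegenerateTripletError

#: A quadratic coefficient smaller than this (in pixel units) is treated as a
#: line, which is not a valid parabola.
DEGENERACY_TOL = 1e-12


class Orientation(str, enum.Enum):
    """Which image axis is the quadratic argument of the parabola."""

    X_OF_Y = "X_OF_Y"  # x = A y^2 + B y + C  (sideways; canonical)
    Y_OF_X = "Y_OF_X"  # y = A x^2 + B x + C


@dataclass(frozen=True)
class PixelPoint:
    """A pixel location: ``x`` is the column, ``y`` the row (0-based)."""

    x: float
    y: float


@dataclass(frozen=True)
class Parabola:
    """General-form parabola ``A t**2 + B t + C = s``.

    For the canonical ``X_OF_Y`` orientation ``t`` is the row coordinate and
    ``s`` the column coordinate.  ``A`` carries units of 1/pixels, ``B`` is
    dimensionless and ``C`` is in pixels.  ``A`` must be nonzero.
    """

    A: float
    B: float
    C: float
    orientation: Orientation = Orientation.X_OF_Y

    def __post_init__(self) -> None:
        if abs(self.A) < DEGENERACY_TOL:
            raise DegenerateTripletError(
                f"quadratic coefficient A={self.A!r} is indistinguishable from a line"
            )

    def to_dict(self) -> dict:
        """JSON-ready representation including derived vertex and aperture."""
        vertex, four_p = vertex_and_aperture(self)
        return {
            "A": self.A,
            "B": self.B,
            "C": self.C,
            "orientation": self.orientation.value,
            "vertex_x": vertex.x,
            "vertex_y": vertex.y,
            "four_p": four_p,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Parabola":
        return cls(
            A=float(d["A"]),
            B=float(d["B"]),
            C=float(d["C"]),
            orientation=Orientation(d.get("orientation", "X_OF_Y")),
        )


def fit_three_points(p1: PixelPoint, p2: PixelPoint, p3: PixelPoint,
                     orientation: Orientation = Orientation.X_OF_Y) -> Parabola:
    """Fit the unique parabola through three pixels in closed form.

    For ``X_OF_Y`` the quadratic argument is the row coordinate ``y``; the
    three rows must be pairwise distinct.  Raises
    :class:`DegenerateTripletError` when two rows coincide or when the
    interpolating polynomial is a line.
    """
    if orientation is Orientation.X_OF_Y:
        (s1, t1), (s2, t2), (s3, t3) = (p1.x, p1.y), (p2.x, p2.y), (p3.x, p3.y)
    else:
        (s1, t1), (s2, t2), (s3, t3) = (p1.y, p1.x), (p2.y, p2.x), (p3.y, p3.x)

    denom = (t1 - t2) * (t1 - t3) * (t2 - t3)
    if denom == 0:
        raise DegenerateTripletError(
            "two of the quadratic-argument coordinates coincide"
        )
    a = (t3 * (s2 - s1) + t2 * (s1 - s3) + t1 * (s3 - s2)) / denom
    b = (t3 * t3 * (s1 - s2) + t2 * t2 * (s3 - s1) + t1 * t1 * (s2 - s3)) / denom
    c = (
        t2 * t3 * (t2 - t3) * s1
        + t3 * t1 * (t3 - t1) * s2
        + t1 * t2 * (t1 - t2) * s3
    ) / denom
    if abs(a) < DEGENERACY_TOL:
        raise DegenerateTripletError("the three points are collinear")
    return Parabola(a, b, c, orientation)


def vertex_and_aperture(p: Parabola) -> Tuple[PixelPoint, float]:
    """Vertex coordinates and aperture (latus rectum) of a parabola.

    The quadratic-argument coordinate of the vertex is ``-B/(2A)`` and the
    other coordinate is ``C - B**2/(4A)``; the aperture is ``4p = 1/A``
    (so ``4p * A == 1`` identically).  For the canonical ``X_OF_Y``
    orientation the vertex row is ``-B/(2A)`` and the vertex column is
    ``C - B**2/(4A)``.
    """
    t_v = -p.B / (2.0 * p.A)
    s_v = p.C - p.B * p.B / (4.0 * p.A)
    four_p = 1.0 / p.A
    if p.orientation is Orientation.X_OF_Y:
        return PixelPoint(x=s_v, y=t_v), four_p
    return PixelPoint(x=t_v, y=s_v), four_p


def evaluate(p: Parabola, t):
    """Evaluate ``A t**2 + B t + C`` at scalar or array argument ``t``."""
    t = np.asarray(t, dtype=float)
    out = (p.A * t + p.B) * t + p.C
    return float(out) if out.ndim == 0 else out


def round_half_away(values):
    """Round to the nearest integer with halves going away from zero.

    numpy's default rounding is half-to-even; detection uses a symmetric,
    locale-independent rule so rasterization is reproducible bit for bit.
    """
    v = np.asarray(values, dtype=float)
    return np.sign(v) * np.floor(np.abs(v) + 0.5)


def rasterize(p: Parabola, height: int, width: int, thickness: int = 0) -> np.ndarray:
    """Render the parabola into a binary ``height x width`` image.

    One pixel per quadratic-argument value: for each integer ``t`` in
    ``[0, height)`` (rows, for the canonical orientation) the column
    ``round(evaluate(p, t))`` is set when it falls inside the frame.  A curve
    entirely out of frame yields an all-zero image.  ``thickness > 0``
    additionally dilates the curve with a disk of that radius, for matching
    against thick edge maps.
    """
    if height <= 0 or width <= 0:
        raise ValueError("image dimensions must be positive")
    if p.orientation is Orientation.Y_OF_X:
        return rasterize(
            Parabola(p.A, p.B, p.C, Orientation.X_OF_Y), width, height, thickness
        ).T
    t = np.arange(height)
    s = round_half_away(evaluate(p, t))
    ok = (s >= 0) & (s < width) & np.isfinite(s)
    img = np.zeros((height, width), dtype=bool)
    img[t[ok], s[ok].astype(np.intp)] = True
    if thickness > 0:
        from skimage.morphology import disk, dilation

        img = dilation(img, disk(thickness))
    return img
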