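"""Conditioning chain that turns a grayscale photograph into an edge image.

The chain is: 3x3 mean filtering, Canny edge detection, then morphological
dilation with a disk structuring element of radius 3.  Dilation closes
slightly open contours and thickens borders, producing the binary image the
detectors consume.  For footprint photographs the image is additionally cut
into three equal horizontal bands (fingers to heel); the middle band contains
the plantar arch and the bottom band the heel, each of which is approximated
by its own parabola.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy.ndimage import uniform_filter
from skimage.feature import canny as _skimage_canny
from skimage.filters import sobel, threshold_otsu
from skimage.morphology import dilation as _dilation, disk

from .errors import EmptyImageError
from .geometry import Orientation, Parabola
from .umda import DetectionResult, EdgeImage, UMDAParams, index_pixels, run


def mean_filter(img: np.ndarray) -> np.ndarray:
    """Smooth with the 3x3 all-ones/9 kernel, replicate padding at borders."""
    return uniform_filter(np.asarray(img, dtype=float), size=3, mode="nearest")


def canny_edges(img: np.ndarray, low: Optional[float] = None,
                high: Optional[float] = None, sigma: float = 1.0) -> EdgeImage:
    """Canny edge map with non-maximum-suppressed, one-pixel-wide edges.

    Hysteresis thresholds apply to the Sobel gradient magnitude.  When not
    given they default to ``high`` = Otsu's threshold of the gradient
    magnitude and ``low = high / 2``.
    """
    img = np.asarray(img, dtype=float)
    if high is None:
        grad = sobel(img)
        high = float(threshold_otsu(grad)) if grad.max() > grad.min() else 0.0
    if low is None:
        low = high / 2.0
    if high > 0 and not low < high:
        raise ValueError("low threshold must be below high threshold")
    edges = _skimage_canny(img, sigma=sigma, low_threshold=low, high_threshold=high)
    return index_pixels(edges, min_pixels=0)


def dilate(img: EdgeImage, radius: int = 3) -> EdgeImage:
    """Morphological dilation with a disk SE (pixels within distance radius)."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    return index_pixels(_dilation(img.grid, disk(radius)), min_pixels=0)


def binarize_chain(img: np.ndarray, low: Optional[float] = None,
                   high: Optional[float] = None, radius: int = 3) -> EdgeImage:
    """Full preprocessing: mean filter, Canny, disk dilation -> f_binary."""
    return dilate(canny_edges(mean_filter(img), low=low, high=high), radius=radius)


# ---------------------------------------------------------------------------
# Footprint sectioning


@dataclass
class FootSections:
    """Three horizontal bands from fingers (top) to heel (bottom).

    Band heights differ by at most one row and sum to the image height;
    remainder rows are assigned to the top band first.  The middle band is the
    plantar-arch region and the bottom band the heel region.
    """

    bands: List[np.ndarray]
    offsets: List[int]

    @property
    def arch(self) -> Tuple[np.ndarray, int]:
        return self.bands[1], self.offsets[1]

    @property
    def heel(self) -> Tuple[np.ndarray, int]:
        return self.bands[2], self.offsets[2]


def section_foot(img: np.ndarray) -> FootSections:
    """Split an image into three near-equal horizontal bands (top gets the
    remainder rows), recording each band's starting row."""
    img = np.asarray(img)
    h = img.shape[0]
    if h < 3:
        raise ValueError("image must have at least 3 rows")
    base, rem = divmod(h, 3)
    heights = [base + (1 if i < rem else 0) for i in range(3)]
    offsets = [0, heights[0], heights[0] + heights[1]]
    bands = [img[off:off + ht] for off, ht in zip(offsets, heights)]
    return FootSections(bands=bands, offsets=offsets)


def _detect_in_band(band_grid: np.ndarray, offset: int,
                    params: UMDAParams, rng) -> DetectionResult:
    """Detect a vertically opening parabola in one horizontal band.

    The band is transposed so the canonical sideways solver applies; the
    result is mapped back to full-image coordinates (row = A col^2 + B col +
    C + offset, i.e. a Y_OF_X parabola).
    """
    edge = index_pixels(band_grid.T)
    res = run(edge, params, rng=rng)
    if res.parabola is not None:
        p = res.parabola
        res.parabola = Parabola(p.A, p.B, p.C + offset, Orientation.Y_OF_X)
    return res


def detect_foot_parabolas(img: np.ndarray, params: Optional[UMDAParams] = None,
                          rng: Optional[np.random.Generator] = None,
                          flip: bool = False,
                          low: Optional[float] = None,
                          high: Optional[float] = None,
                          radius: int = 3) -> Tuple[DetectionResult, DetectionResult]:
    """Approximate the plantar arch and the heel by parabolas.

    Runs the preprocessing chain, sections the edge image into thirds
    (``flip=True`` when the heel is at the top), and runs the evolutionary
    detector inside the arch (middle) and heel (bottom) bands.  Each returned
    parabola opens along the vertical axis with coordinates referring to the
    full image.  Raises :class:`EmptyImageError` when a band holds fewer than
    three edge pixels.
    """
    if params is None:
        params = UMDAParams()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    img = np.asarray(img, dtype=float)
    if flip:
        img = img[::-1]
    binary = binarize_chain(img, low=low, high=high, radius=radius)
    if binary.N < 3:
        raise EmptyImageError("preprocessing produced fewer than 3 edge pixels")
    sections = section_foot(binary.grid)
    arch_band, arch_off = sections.arch
    heel_band, heel_off = sections.heel
    arch = _detect_in_band(arch_band, arch_off, params, rng)
    heel = _detect_in_band(heel_band, heel_off, params, rng)
    return arch, heel
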