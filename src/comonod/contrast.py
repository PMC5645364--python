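"""Contrast maximisation: image-specific threshold from spatial co-occurrence.

The segmentation of dark compact objects (poly-metallic nodules, cells, ...)
from a brighter background is treated as a binary labelling with classes
omega0 (object) and omega1 (background).  Unlike Otsu's method, which looks
only at the grey-value histogram, the threshold here is chosen from the
*spatial* distribution of grey values: a grey-level co-occurrence matrix G
over the four forward Moore offsets scores, for every candidate threshold t,
the fraction gamma(t) of neighbouring-pixel pairs whose two values fall on
the same side of t.  A spatially coherent two-class partition keeps gamma
high; thresholds that cut through coherent regions create many cross-class
pairs and depress it.  The selected threshold sits just below the steepest
rise of gamma, controlled by the parameter theta_gamma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ThresholdSelectionError
from .preprocess import GrayImage

__all__ = [
    "CoocMatrix",
    "CompactnessCurve",
    "BinaryMask",
    "compute_cooc",
    "compactness_curve",
    "curve_derivative",
    "find_peak",
    "select_threshold",
    "binarize",
    "threshold_image",
]

#: Forward Moore offsets (dr, dc): E, S, SE, SW.  With symmetric
#: accumulation these cover each unordered 8-neighbour pair exactly once.
FORWARD_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


@dataclass
class CoocMatrix:
    """Symmetric 256x256 grey-level co-occurrence counts."""

    counts: np.ndarray  # (256, 256) int64

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class CompactnessCurve:
    """gamma(t), its forward difference, the derivative peak and the
    selected threshold for one image."""

    gamma: np.ndarray          # 256 floats in [0, 1]
    dgamma: np.ndarray         # 255 floats
    peak: int
    threshold: int | None      # None when selection failed
    theta_gamma_used: float


@dataclass
class BinaryMask:
    """Two-class image: True = omega0 (object), False = omega1 (background)."""

    pixels: np.ndarray  # bool, (H, W)
    resolution_px_per_cm: float
    threshold_used: int
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def compute_cooc(image: GrayImage | np.ndarray) -> CoocMatrix:
    """Grey-level co-occurrence matrix over the four forward Moore offsets
    at 1 px distance, accumulated symmetrically; off-image neighbours are
    skipped."""
    arr = image.pixels if isinstance(image, GrayImage) else np.asarray(image)
    if arr.ndim != 2 or arr.size < 2:
        raise ConfigurationError(
            "co-occurrence needs a 2-D image with at least one pixel pair")
    arr = arr.astype(np.int64)
    counts = np.zeros((256, 256), dtype=np.int64)
    h, w = arr.shape
    for dr, dc in FORWARD_OFFSETS:
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        a = arr[r0:r1, c0:c1].ravel()
        b = arr[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
        pair = np.bincount(a * 256 + b, minlength=256 * 256).reshape(256, 256)
        counts += pair
    counts += counts.T.copy()
    return CoocMatrix(counts)


def compactness_curve(cooc: CoocMatrix) -> np.ndarray:
    """gamma(t) for all t in [0, 255] via 2-D cumulative sums.

    gamma(t) = (sum_{a<=t, b<=t} G[a,b] + sum_{a>t, b>t} G[a,b]) / sum G.
    gamma(255) = 1 analytically (the second sum is empty, the first is the
    total).
    """
    total = cooc.total
    if total <= 0:
        raise ConfigurationError("empty co-occurrence matrix")
    c2 = cooc.counts.cumsum(axis=0).cumsum(axis=1).astype(np.float64)
    t = np.arange(256)
    low = c2[t, t]
    # High block: total - row-band - col-band + low (inclusion-exclusion).
    high = total - c2[t, 255] - c2[255, t] + low
    return (low + high) / total


def curve_derivative(gamma: np.ndarray) -> np.ndarray:
    """Forward finite difference gamma'(t) = gamma(t+1) - gamma(t)."""
    gamma = np.asarray(gamma, dtype=np.float64)
    return np.diff(gamma)


def smooth_derivative(dgamma: np.ndarray, taps: int = 5) -> np.ndarray:
    """Optional moving-average smoothing of gamma' (off by default)."""
    kernel = np.ones(taps) / taps
    return np.convolve(dgamma, kernel, mode="same")


def find_peak(dgamma: np.ndarray) -> int:
    """Index of the maximum of gamma'; ties break toward the smallest index."""
    dgamma = np.asarray(dgamma)
    if dgamma.size == 0:
        raise ConfigurationError("empty derivative")
    return int(np.argmax(dgamma))


def select_threshold(dgamma: np.ndarray, peak: int, theta_gamma: float) -> int:
    """Highest b < peak with gamma'(b) < gamma'(peak) * theta_gamma.

    Raises :class:`ThresholdSelectionError` when no such b exists (the
    caller skips the image rather than guessing a threshold).
    """
    if not 0.0 < theta_gamma <= 1.0:
        raise ConfigurationError(f"theta_gamma must be in (0, 1], got {theta_gamma}")
    dgamma = np.asarray(dgamma, dtype=np.float64)
    if peak <= 0:
        raise ThresholdSelectionError("derivative peak at 0: no candidate b < peak")
    cut = dgamma[peak] * theta_gamma
    below = np.nonzero(dgamma[:peak] < cut)[0]
    if below.size == 0:
        raise ThresholdSelectionError(
            f"no b < {peak} with gamma'(b) < {cut:.3g}; image skipped"
        )
    return int(below[-1])


def binarize(image: GrayImage, t: int, polarity: str = "dark_objects") -> BinaryMask:
    """Binarise at threshold t: with dark_objects polarity, values <= t
    become omega0 (object); bright_objects flips the comparison."""
    if not 0 <= t <= 255:
        raise ConfigurationError(f"threshold must be in [0, 255], got {t}")
    if polarity == "dark_objects":
        mask = image.pixels <= t
    elif polarity == "bright_objects":
        mask = image.pixels > t
    else:
        raise ConfigurationError(f"unknown polarity {polarity!r}")
    return BinaryMask(mask, image.resolution_px_per_cm, t, image.source_id)


def threshold_image(
    image: GrayImage,
    theta_gamma: float,
    polarity: str = "dark_objects",
    derivative_smoothing: bool = False,
) -> tuple[BinaryMask, CompactnessCurve]:
    """Full phase-1 chain: co-occurrence -> gamma -> gamma' -> peak ->
    threshold -> binary mask.

    Raises :class:`ThresholdSelectionError` when the compactness criterion
    admits no threshold; callers should skip the image and record NaN stats.
    """
    cooc = compute_cooc(image)
    gamma = compactness_curve(cooc)
    dgamma = curve_derivative(gamma)
    d_for_selection = smooth_derivative(dgamma) if derivative_smoothing else dgamma
    peak = find_peak(d_for_selection)
    try:
        t = select_threshold(d_for_selection, peak, theta_gamma)
    except ThresholdSelectionError:
        curve = CompactnessCurve(gamma, dgamma, peak, None, theta_gamma)
        raise ThresholdSelectionError(
            f"{image.source_id or 'image'}: threshold selection failed "
            f"(peak={peak})"
        ) from None
    curve = CompactnessCurve(gamma, dgamma, peak, t, theta_gamma)
    return binarize(image, t, polarity), curve
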