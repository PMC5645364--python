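"""Image normalisation ahead of thresholding.

The fixed pipeline order is: 3x3 median denoise -> rescale to a common
px/cm (factor sqrt(A*/A_i)) -> 3x3 Gaussian smoothing -> illumination /
colour correction -> 8-bit grayscale.  All operations are deterministic
and preserve the image's geo-identity (source_id, px/cm resolution).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .errors import ConfigurationError

__all__ = [
    "GrayImage",
    "median_denoise",
    "compute_scale_factor",
    "rescale",
    "gaussian_smooth",
    "illumination_correct",
    "to_gray",
    "preprocess_image",
]

#: ITU-R BT.601 luminance weights used by to_gray.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

#: Sigma of the 3x3 Gaussian smoothing kernel, in px.
GAUSSIAN_SIGMA = 0.8


@dataclass
class GrayImage:
    """8-bit single-channel raster with physical resolution attached.

    Rescaling multiplies ``resolution_px_per_cm`` by the linear factor so
    that physical sizes stay consistent through the pipeline.
    """

    pixels: np.ndarray  # uint8, shape (H, W)
    resolution_px_per_cm: float
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ConfigurationError("GrayImage requires a 2-D array")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ConfigurationError("grey values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if self.resolution_px_per_cm <= 0:
            raise ConfigurationError("resolution_px_per_cm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _as_array(image):
    return image.pixels if isinstance(image, GrayImage) else np.asarray(image)


def _rewrap(image, pixels: np.ndarray, scale: float = 1.0):
    if isinstance(image, GrayImage):
        return replace(
            image,
            pixels=pixels,
            resolution_px_per_cm=image.resolution_px_per_cm * scale,
        )
    return pixels


def median_denoise(image, window: int = 3):
    """Channel-wise median filter (edge-replicated borders).

    Removes sensor noise and small bright artefacts such as marine-snow
    impulses before any geometric resampling.
    """
    if window % 2 == 0 or window < 3:
        raise ConfigurationError(f"median window must be odd and >= 3, got {window}")
    arr = _as_array(image)
    if arr.ndim == 3:
        out = np.stack(
            [
                ndimage.median_filter(arr[..., c], size=window, mode="nearest")
                for c in range(arr.shape[-1])
            ],
            axis=-1,
        )
    else:
        out = ndimage.median_filter(arr, size=window, mode="nearest")
    return _rewrap(image, out)


def compute_scale_factor(footprint_m2: float, target_footprint_m2: float) -> float:
    """Linear rescaling factor sqrt(A_i / A*).

    Multiplying an image's pixel dimensions by this factor gives every
    image in the set the same px/cm ratio: an image of W px over a ground
    width proportional to sqrt(A_i) has resolution proportional to
    W / sqrt(A_i), so scaling W by sqrt(A_i / A*) makes the resolution
    W / sqrt(A*) for all images.  (Printed as the area ratio A*/A_i in
    the survey-normalisation literature, i.e. the same quantity applied
    as an area divisor.)
    """
    if footprint_m2 <= 0 or target_footprint_m2 <= 0:
        raise ConfigurationError("footprints must be positive")
    return float(np.sqrt(footprint_m2 / target_footprint_m2))


def rescale(image, factor: float):
    """Bicubic rescale by a linear factor; px/cm resolution scales along.

    ``factor == 1`` is a byte-identical no-op.
    """
    if not 0.05 <= factor <= 20.0:
        raise ConfigurationError(f"scale factor {factor} outside sanity bounds [0.05, 20]")
    arr = _as_array(image)
    if factor == 1.0:
        return _rewrap(image, arr.copy())
    h, w = arr.shape[:2]
    out_shape = (max(1, round(h * factor)), max(1, round(w * factor)))
    if arr.ndim == 3:
        out_shape = out_shape + (arr.shape[2],)
    out = resize(
        arr.astype(np.float64),
        out_shape,
        order=3,
        mode="edge",
        anti_aliasing=factor < 1.0,
        preserve_range=True,
    )
    out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return _rewrap(image, out, scale=factor)


def _gaussian_kernel_3x3(sigma: float = GAUSSIAN_SIGMA) -> np.ndarray:
    x = np.arange(-1, 2, dtype=np.float64)
    g = np.exp(-(x**2) / (2.0 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def gaussian_smooth(image, sigma: float = GAUSSIAN_SIGMA):
    """Normalised 3x3 Gaussian smoothing (edge-replicated borders)."""
    arr = _as_array(image)
    k = _gaussian_kernel_3x3(sigma)
    if arr.ndim == 3:
        out = np.stack(
            [
                ndimage.convolve(arr[..., c].astype(np.float64), k, mode="nearest")
                for c in range(arr.shape[-1])
            ],
            axis=-1,
        )
    else:
        out = ndimage.convolve(arr.astype(np.float64), k, mode="nearest")
    out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return _rewrap(image, out)


def _lowpass_field(channel: np.ndarray, lowpass_fraction: float) -> np.ndarray:
    """Smooth illumination/background field estimate.

    Two stages: (a) a grey closing with a square structuring element
    (separable, rolling-ball-style rank filter) fills in dark foreground
    objects so the field tracks the sediment brightness rather than
    dipping wherever objects cluster; (b) a Gaussian low-pass of scale
    ``lowpass_fraction * min(H, W)`` px smooths the closed surface into
    the field.  The closing half-width equals the Gaussian scale, an
    upper bound on the radius of objects to be ignored by the field.
    """
    h, w = channel.shape
    sigma = max(2.0, lowpass_fraction * min(h, w))
    ch = channel.astype(np.float64)
    half = max(2, int(round(sigma)))
    # Odd (antisymmetric) reflection padding: f(-x) = 2 f(0) - f(x).  Plain
    # even reflection (or edge clamping) flattens the illumination ramp at
    # the image border, leaving an under-corrected dark rim that leaks into
    # the foreground mask; odd reflection preserves linear trends.
    pad = min(int(4 * sigma) + half, h - 1, w - 1)
    padded = np.pad(ch, pad, mode="reflect", reflect_type="odd")
    # Pass 1, provisional: grey closing (rolling-ball-style rank filter)
    # fills dark objects, then a Gaussian smooths the surface.  The closing
    # has a small gradient-dependent positive bias, so its output is used
    # only to flag outlier pixels.
    closed = ndimage.grey_closing(padded, size=(2 * half + 1, 2 * half + 1),
                                  mode="nearest")
    field0 = ndimage.gaussian_filter(closed, sigma=sigma, mode="nearest")
    # Pass 2: normalised-convolution Gaussian over inlier pixels only,
    # which removes the dark objects (and any reflection ghosts) without
    # the rank filter's envelope bias.  The inlier band adapts to the
    # background's own spread via a robust MAD scale, with an 8-grey-level
    # floor for quantisation-limited backgrounds.
    dev = padded - field0
    centre = np.median(dev)
    sigma_hat = 1.4826 * np.median(np.abs(dev - centre))
    band = max(8.0, 3.0 * sigma_hat)
    inlier = (np.abs(dev - centre) <= band).astype(np.float64)
    num = ndimage.gaussian_filter(padded * inlier, sigma=sigma, mode="nearest")
    den = ndimage.gaussian_filter(inlier, sigma=sigma, mode="nearest")
    field = np.where(den > 0.05, num / np.maximum(den, 1e-9), field0)
    return field[pad:pad + h, pad:pad + w]


def _equalize_channel(channel: np.ndarray) -> np.ndarray:
    """Global 8-bit histogram equalisation; a single-bin histogram maps to
    itself (identity on constant images)."""
    hist = np.bincount(channel.ravel(), minlength=256)
    nonzero = np.nonzero(hist)[0]
    if nonzero.size <= 1:
        return channel.copy()
    cdf = np.cumsum(hist).astype(np.float64)
    cdf_min = cdf[nonzero[0]]
    total = cdf[-1]
    lut = np.rint((cdf - cdf_min) / (total - cdf_min) * 255.0)
    lut = np.clip(lut, 0, 255).astype(np.uint8)
    return lut[channel]


def illumination_correct(image, lowpass_fraction: float = 0.25,
                         equalize: bool = False):
    """Remove the illumination cone and normalise image brightness.

    Per channel: (a) estimate the smooth illumination field with a Gaussian
    low-pass whose scale is ``lowpass_fraction * min(H, W)`` px; (b)
    subtract it and re-centre at mid-grey 127, which both removes the cone
    and brings every image of a set to a common brightness level; (c)
    optionally apply global histogram equalisation (``equalize=True``).

    Equalisation is off by default: stretching the grey levels in rank
    space amplifies background pixel-pair differences around the sediment
    mode and flattens the co-occurrence compactness structure the
    threshold selection relies on, while the cross-image histogram
    consistency it would provide is already achieved by the common
    re-centring in (b).
    """
    arr = _as_array(image)
    if lowpass_fraction <= 0:
        raise ConfigurationError("lowpass_fraction must be positive")
    if min(arr.shape[:2]) < 4:
        raise ConfigurationError("image smaller than the low-pass kernel")

    def one(ch: np.ndarray) -> np.ndarray:
        field = _lowpass_field(ch, lowpass_fraction)
        # Re-centre at mid-grey.  The half-integer target (126.5) aligns
        # the corrected background with a rounding boundary: its mass
        # splits evenly over two adjacent grey levels instead of piling
        # onto one level with heavy single-level tails, which keeps the
        # below-threshold background leakage minimal in the
        # quantisation-limited regime.  For backgrounds wider than a few
        # levels the 0.5 offset is immaterial.
        flat = ch.astype(np.float64) - field + 126.5
        flat = np.clip(np.rint(flat), 0, 255).astype(np.uint8)
        return _equalize_channel(flat) if equalize else flat

    if arr.ndim == 3:
        out = np.stack([one(arr[..., c]) for c in range(arr.shape[-1])], axis=-1)
    else:
        out = one(arr)
    return _rewrap(image, out)


def to_gray(image, resolution_px_per_cm: float | None = None,
            source_id: str = "") -> GrayImage:
    """Convert a 3-channel 8-bit raster to grayscale with BT.601 weights."""
    if isinstance(image, GrayImage):
        return image
    arr = np.asarray(image)
    if arr.ndim == 2:
        return GrayImage(arr, resolution_px_per_cm or 1.0, source_id)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ConfigurationError("to_gray expects an (H, W, 3) 8-bit raster")
    w = np.asarray(LUMA_WEIGHTS)
    gray = np.clip(np.rint(arr.astype(np.float64) @ w), 0, 255).astype(np.uint8)
    return GrayImage(gray, resolution_px_per_cm or 1.0, source_id)


def preprocess_image(
    raster: np.ndarray,
    resolution_px_per_cm: float,
    source_id: str,
    footprint_m2: float,
    target_footprint_m2: float,
    lowpass_fraction: float = 0.25,
) -> GrayImage:
    """Run the full normalisation chain on one raw raster.

    Order: median -> rescale -> Gaussian -> illumination correction ->
    grayscale.  Returns the 8-bit grayscale image ready for thresholding,
    with its px/cm resolution updated by the rescale step.
    """
    arr = median_denoise(raster, 3)
    factor = compute_scale_factor(footprint_m2, target_footprint_m2)
    arr = rescale(arr, factor)
    arr = gaussian_smooth(arr)
    arr = illumination_correct(arr, lowpass_fraction)
    gray = to_gray(arr, resolution_px_per_cm * factor, source_id)
    return gray
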