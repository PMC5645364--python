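"""End-to-end processing: raw raster -> nodule table -> abundance statistics."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .contrast import BinaryMask, CompactnessCurve, threshold_image
from .delineate import Nodule, delineate_mask
from .errors import ThresholdSelectionError
from .io_config import RunConfig
from .preprocess import GrayImage, preprocess_image
from .stats_grid import AbundanceStats, image_stats

log = logging.getLogger(__name__)

__all__ = ["ImageResult", "process_array", "process_gray"]


@dataclass
class ImageResult:
    """Everything the pipeline produced for one image.

    ``skipped`` is set (and ``nodules`` empty, statistics NaN) when
    threshold selection failed; such images are reported, never guessed at.
    """

    image_id: str
    nodules: list[Nodule]
    stats: AbundanceStats
    curve: CompactnessCurve | None
    mask: BinaryMask | None
    gray: GrayImage | None
    skipped: bool = False

    @property
    def threshold(self) -> int | None:
        return None if self.curve is None else self.curve.threshold


def process_gray(gray: GrayImage, config: RunConfig, footprint_m2: float,
                 keep_intermediates: bool = False) -> ImageResult:
    """Phase 1 + phase 2 + statistics on an already-preprocessed image."""
    try:
        mask, curve = threshold_image(
            gray,
            config.theta_gamma,
            config.binarisation_polarity,
            config.derivative_smoothing,
        )
    except ThresholdSelectionError as exc:
        log.warning("%s", exc)
        nan_stats = image_stats([], footprint_m2)
        nan_stats.phi_N = float("nan")
        nan_stats.phi_C = float("nan")
        return ImageResult(gray.source_id, [], nan_stats, None, None,
                           gray if keep_intermediates else None, skipped=True)
    nodules = delineate_mask(mask, config.theta_r, image_id=gray.source_id)
    stats = image_stats(nodules, footprint_m2, image_shape=gray.shape)
    return ImageResult(
        gray.source_id,
        nodules,
        stats,
        curve,
        mask if keep_intermediates else None,
        gray if keep_intermediates else None,
    )


def process_array(
    raster: np.ndarray,
    resolution_px_per_cm: float,
    footprint_m2: float,
    config: RunConfig,
    target_footprint_m2: float | None = None,
    image_id: str = "",
    keep_intermediates: bool = False,
) -> ImageResult:
    """Full pipeline on a raw 8-bit raster (grayscale or colour).

    ``target_footprint_m2`` defaults to the image's own footprint (no
    rescaling), which is the single-image / preview case; batch runs pass
    the set median A*.
    """
    target = footprint_m2 if target_footprint_m2 is None else target_footprint_m2
    gray = preprocess_image(
        raster,
        resolution_px_per_cm,
        image_id,
        footprint_m2,
        target,
        lowpass_fraction=config.lowpass_fraction,
    )
    return process_gray(gray, config, footprint_m2,
                        keep_intermediates=keep_intermediates)
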