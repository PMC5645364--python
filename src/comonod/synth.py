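"""Synthetic seafloor-survey scenes with exact ground truth.

Scenes emulate nadir photographs of poly-metallic nodule fields: dark,
roughly elliptical objects on a brighter textured sediment background, an
illumination cone (centre brighter than the corners), additive sensor
noise, bright marine-snow speckles and partial sediment dusting of the
objects.  Every scene is a pure function of (spec, seed): the same pair
yields byte-identical images, and the returned ground truth carries the
analytic ellipse parameters so geometry error can be separated from
detection error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SceneGenerationError
from .io_config import SIZE_ALPHAS
from .stats_grid import AbundanceStats, image_stats, size_quantiles, trask_descriptors

__all__ = ["SceneSpec", "GroundTruth", "generate_scene", "truth_stats"]


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    Defaults emulate a low-altitude nadir photo survey of a nodule field
    (~1 m above the seafloor at a 90° field of view): a ~1 Mpx frame at
    5 px/cm (a 2.05 m x 2.05 m footprint, 4.2 m²), right-skewed lognormal
    nodule sizes with a median of 48.6 cm² (equivalent radius ~3.9 cm,
    ~20 px), about 5 % seafloor coverage (36 objects per frame), one
    object in five planted touching a neighbour, smooth metre-scale
    sediment-albedo texture of ±2.5 grey levels, a 30 % illumination
    cone, occasional marine-snow speckles, and strobe-lit base-ISO
    sensor noise of sigma 0.5 grey levels against an object/sediment
    contrast of 90 levels.
    """

    width_px: int = 1024
    height_px: int = 1024
    resolution_px_per_cm: float = 5.0
    n_objects: int = 36
    size_log_mu: float = math.log(48.6)   # lognormal of area in cm²
    size_log_sigma: float = 0.6
    axis_ratio_range: tuple[float, float] = (1.0, 2.0)
    overlap_fraction: float = 0.2
    object_grey_mean: float = 60.0
    object_grey_std: float = 6.0
    background_grey_mean: float = 150.0
    background_grey_std: float = 2.5
    background_texture_scale_px: int = 512
    noise_sigma: float = 0.5
    illumination_amplitude: float = 0.3
    illumination_sigma_frac: float = 0.45
    speckle_rate_per_mpx: float = 100.0
    occlusion_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.object_grey_mean >= self.background_grey_mean:
            raise ConfigurationError(
                "object_grey_mean must be below background_grey_mean (dark objects)"
            )
        for name in ("overlap_fraction", "occlusion_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for name in ("noise_sigma", "speckle_rate_per_mpx", "illumination_amplitude"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0 < self.illumination_amplitude < 1 and self.illumination_amplitude != 0:
            raise ConfigurationError("illumination_amplitude must be in [0, 1)")

    @property
    def footprint_m2(self) -> float:
        gw = self.width_px / (100.0 * self.resolution_px_per_cm)
        gh = self.height_px / (100.0 * self.resolution_px_per_cm)
        return gw * gh


@dataclass
class GroundTruth:
    """Exact per-object geometry and the abundance statistics derived from it."""

    labels: np.ndarray            # uint16, 0 = background, j = object j
    objects: pd.DataFrame         # one row per planted object
    phi_N: float
    phi_C: float
    phi_S: dict[float, float]
    area_m2: float


def _ellipse_coverage(
    h: int, w: int, cy: float, cx: float, a: float, b: float, phi_deg: float,
    supersample: int = 4,
) -> tuple[slice, slice, np.ndarray]:
    """Anti-aliased coverage (0..1) of an ellipse over its bounding box.

    phi_deg is the display-convention orientation: the angle of the major
    axis from the +col axis toward the -row axis, in degrees.
    """
    phi = math.radians(phi_deg)
    r0 = max(0, int(math.floor(cy - a - 1)))
    r1 = min(h, int(math.ceil(cy + a + 1)) + 1)
    c0 = max(0, int(math.floor(cx - a - 1)))
    c1 = min(w, int(math.ceil(cx + a + 1)) + 1)
    if r0 >= r1 or c0 >= c1:
        return slice(0, 0), slice(0, 0), np.zeros((0, 0))
    s = supersample
    # Supersample pixel centres: offsets (k + 0.5)/s - 0.5 within the pixel.
    sub = (np.arange(s) + 0.5) / s - 0.5
    rows = (np.arange(r0, r1)[:, None] + sub[None, :]).ravel()
    cols = (np.arange(c0, c1)[:, None] + sub[None, :]).ravel()
    dr = rows[:, None] - cy
    dc = cols[None, :] - cx
    u = -dr * math.sin(phi) + dc * math.cos(phi)
    v = -dr * math.cos(phi) - dc * math.sin(phi)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    cov = inside.reshape(r1 - r0, s, c1 - c0, s).mean(axis=(1, 3))
    return slice(r0, r1), slice(c0, c1), cov


def _sample_objects(spec: SceneSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Rejection-sample ellipse placements.

    A fraction ``1 - overlap_fraction`` of objects is planted with clear
    separation (boundary margin > 2 px to every earlier object, measured on
    bounding circles); the remaining objects are deliberately placed
    touching a randomly chosen earlier object.
    """
    res = spec.resolution_px_per_cm
    n = spec.n_objects
    areas_cm2 = rng.lognormal(spec.size_log_mu, spec.size_log_sigma, size=n)
    ratios = rng.uniform(*spec.axis_ratio_range, size=n)
    phis = rng.uniform(0.0, 180.0, size=n)
    # area = pi a b, ratio = a/b  =>  b = sqrt(area / (pi ratio))
    b_cm = np.sqrt(areas_cm2 / (math.pi * ratios))
    a_cm = b_cm * ratios
    a_px, b_px = a_cm * res, b_cm * res

    n_touching = int(round(spec.overlap_fraction * n))
    placed: list[dict] = []
    pc = np.empty((0, 2))   # placed centres
    pa = np.empty(0)        # placed bounding radii (semi-major)
    pb = np.empty(0)        # placed semi-minor
    h, w = spec.height_px, spec.width_px
    max_tries = 2000
    for j in range(n):
        a, b = float(a_px[j]), float(b_px[j])
        touching = bool(j >= n - n_touching and placed)
        for attempt in range(max_tries):
            if touching:
                k = int(rng.integers(len(placed)))
                ang = rng.uniform(0, 2 * math.pi)
                # Bounding circles overlap a little, without near-total
                # occlusion of either object.
                d = rng.uniform(0.6, 0.95) * (a + pa[k])
                cy = pc[k, 0] + d * math.sin(ang)
                cx = pc[k, 1] + d * math.cos(ang)
            else:
                cy = rng.uniform(a, h - a)
                cx = rng.uniform(a, w - a)
            if not (a <= cy <= h - a and a <= cx <= w - a):
                continue
            if len(placed) == 0:
                break
            dist = np.hypot(pc[:, 0] - cy, pc[:, 1] - cx)
            if touching:
                if (dist >= 0.5 * np.maximum(b, pb)).all():
                    break
            elif (dist >= pa + a + 2.0).all():
                break
        else:
            raise SceneGenerationError(
                f"could not place object {j} after {max_tries} tries "
                "(density infeasible)"
            )
        placed.append(
            {
                "object_id": j + 1,
                "cy": cy,
                "cx": cx,
                "a_px": a,
                "b_px": b,
                "orientation_deg": float(phis[j]),
                "area_cm2": float(areas_cm2[j]),
                "touching": touching,
            }
        )
        pc = np.vstack([pc, (cy, cx)])
        pa = np.append(pa, a)
        pb = np.append(pb, b)
    return pd.DataFrame(placed)


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one scene and its exact ground truth.

    Returns an (H, W) uint8 image and a :class:`GroundTruth` whose object
    table carries the analytic ellipse parameters (true area = pi a b in
    cm², independent of rasterisation).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    objects = _sample_objects(spec, rng) if spec.n_objects > 0 else pd.DataFrame(
        columns=["object_id", "cy", "cx", "a_px", "b_px",
                 "orientation_deg", "area_cm2", "touching"]
    )

    # Sediment background: smooth bedform-scale texture.
    ts = max(2, spec.background_texture_scale_px)
    coarse = rng.normal(0.0, 1.0, size=(h // ts + 2, w // ts + 2))
    from skimage.transform import resize as _resize

    texture = _resize(coarse, (h, w), order=3, mode="edge",
                      anti_aliasing=False, preserve_range=True)
    img = spec.background_grey_mean + spec.background_grey_std * texture

    labels = np.zeros((h, w), dtype=np.uint16)
    for row in objects.itertuples():
        rs, cs, cov = _ellipse_coverage(
            h, w, row.cy, row.cx, row.a_px, row.b_px, row.orientation_deg
        )
        if cov.size == 0:
            continue
        grey = rng.normal(spec.object_grey_mean, spec.object_grey_std)
        img[rs, cs] = (1.0 - cov) * img[rs, cs] + cov * grey
        labels[rs, cs][cov >= 0.5] = row.object_id

    # Partial sediment occlusion: dust a fraction of each object's pixels
    # back to background grey (single-pixel dust, removed by median denoise).
    if spec.occlusion_fraction > 0 and len(objects):
        obj_pix = np.nonzero(labels > 0)
        n_dust = int(spec.occlusion_fraction * obj_pix[0].size)
        if n_dust:
            pick = rng.choice(obj_pix[0].size, size=n_dust, replace=False)
            img[obj_pix[0][pick], obj_pix[1][pick]] = spec.background_grey_mean

    # Illumination cone: multiplicative Gaussian gain, centre = 1.
    if spec.illumination_amplitude > 0:
        yy, xx = np.mgrid[0:h, 0:w]
        sig = spec.illumination_sigma_frac * min(h, w)
        r2 = (yy - (h - 1) / 2.0) ** 2 + (xx - (w - 1) / 2.0) ** 2
        gain = (1.0 - spec.illumination_amplitude) + \
            spec.illumination_amplitude * np.exp(-r2 / (2.0 * sig**2))
        img *= gain

    # Marine-snow speckles: bright single-pixel impulses.
    n_speckle = rng.poisson(spec.speckle_rate_per_mpx * h * w / 1e6)
    if n_speckle:
        sr = rng.integers(0, h, size=n_speckle)
        sc = rng.integers(0, w, size=n_speckle)
        img[sr, sc] = 255.0

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=(h, w))

    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    area_m2 = spec.footprint_m2
    if len(objects):
        sizes = objects["area_cm2"].to_numpy()
        phi_n = len(objects) / area_m2
        phi_c = 100.0 * sizes.sum() / 1e4 / area_m2
        phi_s = size_quantiles(sizes)
    else:
        phi_n = 0.0
        phi_c = 0.0
        phi_s = {a: float("nan") for a in SIZE_ALPHAS}
    gt = GroundTruth(labels, objects, phi_n, phi_c, phi_s, area_m2)
    return img, gt


def truth_stats(gt: GroundTruth, area_m2: float | None = None) -> AbundanceStats:
    """Abundance statistics recomputed from the ground-truth object table
    (the recovery reference for pipeline tests)."""
    area = gt.area_m2 if area_m2 is None else area_m2
    if len(gt.objects) == 0:
        return image_stats([], area)
    sizes = gt.objects["area_cm2"].to_numpy()
    phi_s = size_quantiles(sizes)
    sorting, skew = trask_descriptors(phi_s)
    return AbundanceStats(
        n_nodules=len(gt.objects),
        phi_N=len(gt.objects) / area,
        phi_C=100.0 * sizes.sum() / 1e4 / area,
        phi_S=phi_s,
        trask_sorting=sorting,
        trask_skewness=skew,
        area_m2=area,
    )
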