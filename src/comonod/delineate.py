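"""Object delineation: from the binary mask to individual ellipse-fitted objects.

The binary mask is turned into single-object blobs in five steps: Euclidean
distance map, local-maximum candidate centroids, greedy non-maximum
suppression within a 5*theta_r radius, marker-controlled watershed on the
negated distance map (which cuts merged blobs at their distance-map
bottlenecks), and fusion/discard of fragments smaller than pi*theta_r**2 px.
Surviving blobs are delineated by their convex hull (closing gaps caused by
sediment cover) and fitted with an ellipse whose axes give the object size
in cm².
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import EllipseModel
from skimage.segmentation import watershed

from .contrast import BinaryMask
from .errors import ConfigurationError

__all__ = [
    "DistanceMap",
    "PeakSet",
    "Nodule",
    "distance_map",
    "local_maxima",
    "suppress_peaks",
    "split_blobs",
    "fuse_small_blobs",
    "convex_hulls",
    "fit_ellipse",
    "delineate_mask",
]

log = logging.getLogger(__name__)

_EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity structure


@dataclass
class DistanceMap:
    """Per-pixel Euclidean distance to the nearest background pixel."""

    values: np.ndarray  # float64, same shape as the mask


@dataclass
class PeakSet:
    """Candidate object centroids: (row, col, height) on the distance map."""

    peaks: list[tuple[int, int, float]]

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class Nodule:
    """One delineated object: fitted-ellipse geometry plus physical size.

    ``size_cm2`` is pi * semi_major_cm * semi_minor_cm from the fitted
    ellipse (not the raw pixel count); ``area_px`` keeps the pixel count of
    the final blob for diagnostics.
    """

    id: int
    centroid: tuple[float, float]       # (row, col) in px
    semi_major_px: float
    semi_minor_px: float
    orientation_deg: float              # in [0, 180)
    area_px: int
    resolution_px_per_cm: float
    image_id: str = ""

    def __post_init__(self) -> None:
        if not self.semi_major_px >= self.semi_minor_px > 0:
            raise ConfigurationError("ellipse axes must satisfy a >= b > 0")

    @property
    def semi_major_cm(self) -> float:
        return self.semi_major_px / self.resolution_px_per_cm

    @property
    def semi_minor_cm(self) -> float:
        return self.semi_minor_px / self.resolution_px_per_cm

    @property
    def size_cm2(self) -> float:
        return math.pi * self.semi_major_cm * self.semi_minor_cm


def distance_map(mask: BinaryMask) -> DistanceMap:
    """Exact Euclidean distance from each object pixel to the nearest
    background pixel.  For an all-object mask the distance to the image
    border is used instead (there is no background pixel to measure to)."""
    m = mask.pixels
    if m.size == 0:
        raise ConfigurationError("empty mask")
    if m.all():
        padded = np.pad(m, 1, constant_values=False)
        d = ndimage.distance_transform_edt(padded)[1:-1, 1:-1]
    else:
        d = ndimage.distance_transform_edt(m)
    return DistanceMap(np.asarray(d, dtype=np.float64))


def local_maxima(dist: DistanceMap) -> PeakSet:
    """Pixels whose distance value is >= all 8 Moore neighbours and > 0.

    A flat plateau of equal-valued maxima contributes a single
    representative: the topmost-leftmost pixel of its 8-connected component.
    """
    d = dist.values
    cand = (d == ndimage.maximum_filter(d, size=3, mode="constant", cval=-1.0)) & (d > 0)
    if not cand.any():
        return PeakSet([])
    labels, n = ndimage.label(cand, structure=_EIGHT)
    peaks: list[tuple[int, int, float]] = []
    rows, cols = np.nonzero(labels)
    order = np.lexsort((cols, rows))  # row-major scan
    seen: set[int] = set()
    for i in order:
        lab = labels[rows[i], cols[i]]
        if lab not in seen:
            seen.add(lab)
            r, c = int(rows[i]), int(cols[i])
            peaks.append((r, c, float(d[r, c])))
    return PeakSet(peaks)


def suppress_peaks(peaks: PeakSet, theta_r: int) -> PeakSet:
    """Greedy non-maximum suppression: visit peaks by descending height
    (ties in row-major order) and accept each one iff no already-accepted
    peak lies within Euclidean distance 5*theta_r.

    A peak's height is the inscribed-circle radius of its blob at that
    point; candidates with height < theta_r are below the minimum nodule
    radius and are dropped up front.  This removes the thin, straggly
    false-foreground structures that grey-level leakage produces, which
    can exceed the pi*theta_r**2 area cut-off while never being wider
    than a real nodule.
    """
    if theta_r < 1:
        raise ConfigurationError(f"theta_r must be >= 1, got {theta_r}")
    radius = 5.0 * theta_r
    candidates = [p for p in peaks.peaks if p[2] >= theta_r]
    order = sorted(candidates, key=lambda p: (-p[2], p[0], p[1]))
    kept: list[tuple[int, int, float]] = []
    if order:
        kept_rc = np.empty((0, 2))
        for r, c, h in order:
            if kept_rc.size:
                d2 = ((kept_rc - (r, c)) ** 2).sum(axis=1)
                if (d2 <= radius * radius).any():
                    continue
            kept.append((r, c, h))
            kept_rc = np.vstack([kept_rc, (r, c)])
    return PeakSet(kept)


def split_blobs(mask: BinaryMask, peaks: PeakSet, dist: DistanceMap) -> np.ndarray:
    """Assign every object pixel to exactly one retained peak via
    marker-controlled watershed on the negated distance map.

    The watershed cuts merged blobs at distance-map bottlenecks (the
    narrow necks between touching objects).  Blobs containing no retained
    peak stay unlabeled (0) and are dealt with by fusion/discard.
    Termination is guaranteed: exactly one region per marker.
    """
    markers = np.zeros(mask.shape, dtype=np.int32)
    for j, (r, c, _h) in enumerate(peaks.peaks, start=1):
        if not mask.pixels[r, c]:
            raise ConfigurationError(f"peak ({r}, {c}) not on an object pixel")
        markers[r, c] = j
    if not peaks.peaks:
        return markers
    return watershed(-dist.values, markers=markers, mask=mask.pixels,
                     connectivity=2).astype(np.int32)


def _blob_areas(labels: np.ndarray) -> dict[int, int]:
    counts = np.bincount(labels.ravel())
    return {lab: int(counts[lab]) for lab in range(1, counts.size) if counts[lab] > 0}


def _neighbours_within(labels: np.ndarray, lab: int, max_dist: float) -> dict[int, int]:
    """Blob labels whose minimum boundary-to-boundary Euclidean distance to
    blob ``lab`` is strictly below ``max_dist``, with their areas.

    Works on a window around the blob's bounding box, padded by the search
    distance, using an EDT seeded at the blob.
    """
    rows, cols = np.nonzero(labels == lab)
    pad = int(math.ceil(max_dist)) + 1
    r0, r1 = max(0, rows.min() - pad), min(labels.shape[0], rows.max() + pad + 1)
    c0, c1 = max(0, cols.min() - pad), min(labels.shape[1], cols.max() + pad + 1)
    win = labels[r0:r1, c0:c1]
    dist_from_blob = ndimage.distance_transform_edt(win != lab)
    near = (dist_from_blob < max_dist) & (win > 0) & (win != lab)
    cand = np.unique(win[near])
    areas = np.bincount(labels.ravel())
    return {int(l): int(areas[l]) for l in cand}


def fuse_small_blobs(labels: np.ndarray, theta_r: int) -> np.ndarray:
    """Fuse blobs smaller than pi*theta_r**2 px with their largest neighbour
    closer than 2*theta_r px (boundary-to-boundary); discard them when no
    such neighbour exists.  Small blobs are visited in ascending area order
    and the pass repeats until nothing changes."""
    if theta_r < 1:
        raise ConfigurationError(f"theta_r must be >= 1, got {theta_r}")
    labels = labels.copy()
    area_cutoff = math.pi * theta_r**2
    fuse_dist = 2.0 * theta_r
    changed = True
    while changed:
        changed = False
        areas = _blob_areas(labels)
        small = sorted((a, lab) for lab, a in areas.items() if a < area_cutoff)
        for _a, lab in small:
            if not (labels == lab).any():
                continue  # already absorbed this pass
            cands = _neighbours_within(labels, lab, fuse_dist)
            if cands:
                target = max(cands, key=lambda l: (cands[l], -l))
                labels[labels == lab] = target
            else:
                labels[labels == lab] = 0
            changed = True
    return labels


def convex_hulls(labels: np.ndarray) -> dict[int, np.ndarray]:
    """Convex hull vertices (row, col) of each surviving blob.

    Blobs with fewer than 3 pixels or collinear pixel sets cannot carry a
    2-D hull and are discarded with a log entry.
    """
    hulls: dict[int, np.ndarray] = {}
    for lab in sorted(_blob_areas(labels)):
        pts = np.column_stack(np.nonzero(labels == lab)).astype(np.float64)
        if len(pts) < 3:
            log.info("blob %d: fewer than 3 pixels, discarded", lab)
            continue
        try:
            hull = ConvexHull(pts)
        except QhullError:
            log.info("blob %d: degenerate (collinear) pixel set, discarded", lab)
            continue
        hulls[lab] = pts[hull.vertices]
    return hulls


def _moment_ellipse(points: np.ndarray) -> tuple[float, float, float, float, float]:
    """Moment-based ellipse for degenerate hulls (3-4 points): centre at the
    point mean, axes 2*sqrt(eigenvalues) of the coordinate covariance."""
    centre = points.mean(axis=0)
    cov = np.cov((points - centre).T)
    evals, evecs = np.linalg.eigh(cov)
    evals = np.maximum(evals, 1e-12)
    order = np.argsort(evals)[::-1]
    a, b = 2.0 * np.sqrt(evals[order])
    vy, vx = evecs[:, order[0]]  # (row, col) components of the major axis
    theta = math.degrees(math.atan2(-vy, vx)) % 180.0
    return centre[0], centre[1], float(a), float(b), theta


def fit_ellipse(
    hull: np.ndarray,
    resolution_px_per_cm: float,
    nodule_id: int = 0,
    area_px: int = 0,
    image_id: str = "",
) -> Nodule | None:
    """Least-squares ellipse through the hull vertices.

    Uses the direct conic fit for >= 5 points and a moment-based ellipse
    for 3-4 points.  Hull pixel coordinates are offset by +0.5 axis units
    conceptually representing pixel centres; the fit treats them as exact
    points.  Returns None (with a log entry) when the fit degenerates.
    """
    hull = np.asarray(hull, dtype=np.float64)
    if len(hull) < 3:
        log.info("nodule %d: fewer than 3 hull points, rejected", nodule_id)
        return None
    a = b = None
    if len(hull) >= 5:
        # EllipseModel works in (x, y); feed (col, row).  Degenerate hulls
        # can make the conic solve blow up; fall back to moments then.
        try:
            with np.errstate(all="ignore"):
                model = EllipseModel.from_estimate(hull[:, ::-1])
        except (TypeError, ValueError, np.linalg.LinAlgError):
            model = None
        if model and np.all(np.isfinite(model.center)) \
                and np.all(np.isfinite(model.axis_lengths)):
            (xc, yc), (ax0, ax1), theta = model.center, model.axis_lengths, model.theta
            a, b = (ax0, ax1) if ax0 >= ax1 else (ax1, ax0)
            if ax0 < ax1:
                theta += math.pi / 2.0
            cy, cx = yc, xc
            orient = math.degrees(-theta) % 180.0
    if a is None:
        cy, cx, a, b, orient = _moment_ellipse(hull)
    # an ellipse thinner than half a pixel is a collinear degenerate
    if not (np.isfinite(a) and np.isfinite(b)) or b <= 0.5 or a <= 0:
        log.info("nodule %d: degenerate ellipse fit, rejected", nodule_id)
        return None
    return Nodule(
        id=nodule_id,
        centroid=(float(cy), float(cx)),
        semi_major_px=float(a),
        semi_minor_px=float(b),
        orientation_deg=float(orient),
        area_px=int(area_px),
        resolution_px_per_cm=resolution_px_per_cm,
        image_id=image_id,
    )


def delineate_mask(mask: BinaryMask, theta_r: int, image_id: str = "") -> list[Nodule]:
    """Full phase-2 chain: distance map -> peaks -> suppression -> watershed
    split -> small-blob fusion -> convex hulls -> ellipse fits."""
    dist = distance_map(mask)
    peaks = suppress_peaks(local_maxima(dist), theta_r)
    labels = fuse_small_blobs(split_blobs(mask, peaks, dist), theta_r)
    hulls = convex_hulls(labels)
    areas = _blob_areas(labels)
    nodules: list[Nodule] = []
    for j, lab in enumerate(sorted(hulls), start=1):
        nod = fit_ellipse(
            hulls[lab],
            mask.resolution_px_per_cm,
            nodule_id=j,
            area_px=areas.get(lab, 0),
            image_id=image_id or mask.source_id,
        )
        if nod is not None:
            nodules.append(nod)
    return nodules
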