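"""Abundance statistics per image and geo-referenced gridding.

From the per-object sizes s_j (cm²) of an image covering A m² of seafloor,
the abundance descriptors are:

* Phi^N = N / A            — objects per m²
* Phi^c = sum(s_j) / A     — percent seafloor coverage (for whole images the
  union of the clipped fitted ellipses is used instead of the plain sum, so
  overlapping fits can never push coverage past 100 %)
* Phi^s_alpha              — the size below which a fraction alpha of the
  total coverage is accumulated, for alpha in
  {0.01, 0.10, 0.25, 0.5, 0.75, 0.90, 0.99}
* Trask sorting 0.5*(Phi^s_0.75 - Phi^s_0.25) and skewness
  Phi^s_0.75 + Phi^s_0.25 - 2*Phi^s_0.5 — classical particle-size spread
  and asymmetry descriptors.

Gridding tiles each image footprint into square cells on a common
geographic grid and pools the per-image cell statistics (default: max).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .delineate import Nodule
from .errors import ConfigurationError
from .io_config import SIZE_ALPHAS, ImageRecord

__all__ = [
    "AbundanceStats",
    "GridCell",
    "image_stats",
    "size_quantiles",
    "trask_descriptors",
    "equivalent_radius",
    "coverage_union_fraction",
    "grid_aggregate",
    "export_map",
    "nodule_table",
]

#: Mean Earth radius used by the local equirectangular metric, in metres.
EARTH_RADIUS_M = 6_371_000.0


@dataclass
class AbundanceStats:
    """Abundance descriptors for one image or grid cell."""

    n_nodules: int
    phi_N: float                 # objects per m²
    phi_C: float                 # percent coverage, in [0, 100]
    phi_S: dict[float, float]    # alpha -> size in cm²
    trask_sorting: float         # cm²
    trask_skewness: float        # cm²
    area_m2: float

    def as_row(self) -> dict[str, float]:
        row = {
            "n_nodules": self.n_nodules,
            "phi_N": self.phi_N,
            "phi_C": self.phi_C,
            "trask_sorting": self.trask_sorting,
            "trask_skewness": self.trask_skewness,
            "area_m2": self.area_m2,
        }
        for a in SIZE_ALPHAS:
            row[f"phi_S_{a:g}"] = self.phi_S.get(a, float("nan"))
        return row


@dataclass
class GridCell:
    """One cell of the abundance map."""

    cell_row: int
    cell_col: int
    latitude: float
    longitude: float
    stats: AbundanceStats
    n_contributing_images: int = 1


def size_quantiles(sizes, alphas=SIZE_ALPHAS) -> dict[float, float]:
    """Characteristic sizes along the coverage accumulation curve.

    Sizes are sorted ascending; for each alpha, k_alpha is the largest k
    whose cumulative size sum stays strictly below alpha * total, and
    Phi^s_alpha = s[k_alpha].  When even the smallest size fails the strict
    bound, Phi^s_alpha = s[0].
    """
    s = np.sort(np.asarray(list(sizes), dtype=np.float64))
    if s.size == 0:
        raise ConfigurationError("size_quantiles: empty size list")
    cum = np.cumsum(s)
    total = cum[-1]
    out: dict[float, float] = {}
    for a in alphas:
        below = np.nonzero(cum < a * total)[0]
        k = int(below[-1]) if below.size else 0
        out[a] = float(s[k])
    return out


def trask_descriptors(phi_S: dict[float, float]) -> tuple[float, float]:
    """Trask sorting and skewness from the 25/50/75 % accumulation sizes.

    NaN quantiles propagate NaN.
    """
    try:
        q25, q50, q75 = phi_S[0.25], phi_S[0.5], phi_S[0.75]
    except KeyError as exc:
        raise ConfigurationError(f"missing quantile {exc} for Trask descriptors")
    sorting = 0.5 * (q75 - q25)
    skewness = q75 + q25 - 2.0 * q50
    return float(sorting), float(skewness)


def equivalent_radius(size_cm2: float) -> float:
    """Radius in cm of the circle with the given area: sqrt(size / pi)."""
    if size_cm2 <= 0:
        raise ConfigurationError(f"size must be positive, got {size_cm2}")
    return math.sqrt(size_cm2 / math.pi)


def coverage_union_fraction(
    nodules: list[Nodule], shape: tuple[int, int]
) -> float:
    """Fraction of the image covered by the union of the fitted ellipses,
    each clipped to the image frame.  Bounded by 1 regardless of overlaps."""
    h, w = shape
    covered = np.zeros((h, w), dtype=bool)
    for nod in nodules:
        cy, cx = nod.centroid
        a, b = nod.semi_major_px, nod.semi_minor_px
        phi = math.radians(nod.orientation_deg)
        r0 = max(0, int(math.floor(cy - a)))
        r1 = min(h, int(math.ceil(cy + a)) + 1)
        c0 = max(0, int(math.floor(cx - a)))
        c1 = min(w, int(math.ceil(cx + a)) + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        rr, cc = np.mgrid[r0:r1, c0:c1]
        dr, dc = rr - cy, cc - cx
        u = -dr * math.sin(phi) + dc * math.cos(phi)
        v = -dr * math.cos(phi) - dc * math.sin(phi)
        covered[r0:r1, c0:c1] |= (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return float(covered.mean())


def image_stats(
    nodules: list[Nodule],
    area_m2: float,
    image_shape: tuple[int, int] | None = None,
) -> AbundanceStats:
    """Abundance descriptors for one image (or tile) of seafloor area A m².

    Coverage Phi^c uses the clipped-ellipse union when ``image_shape`` is
    given (whole-image statistics), else the plain size sum (tile-level or
    table-only statistics).  An empty nodule list yields Phi^N = Phi^c = 0
    with NaN size quantiles.
    """
    if area_m2 <= 0:
        raise ConfigurationError(f"area_m2 must be positive, got {area_m2}")
    n = len(nodules)
    if n == 0:
        nan = float("nan")
        return AbundanceStats(0, 0.0, 0.0, {a: nan for a in SIZE_ALPHAS},
                              nan, nan, area_m2)
    sizes = [nod.size_cm2 for nod in nodules]
    if image_shape is not None:
        phi_c = 100.0 * coverage_union_fraction(nodules, image_shape)
    else:
        phi_c = 100.0 * (sum(sizes) / 1e4) / area_m2
    phi_s = size_quantiles(sizes)
    sorting, skewness = trask_descriptors(phi_s)
    return AbundanceStats(
        n_nodules=n,
        phi_N=n / area_m2,
        phi_C=phi_c,
        phi_S=phi_s,
        trask_sorting=sorting,
        trask_skewness=skewness,
        area_m2=area_m2,
    )


def nodule_table(nodules: list[Nodule]) -> pd.DataFrame:
    """Per-image nodule table (one row per delineated object)."""
    rows = []
    for nod in nodules:
        rows.append(
            {
                "image_id": nod.image_id,
                "nodule_id": nod.id,
                "centroid_row": nod.centroid[0],
                "centroid_col": nod.centroid[1],
                "semi_major_cm": nod.semi_major_cm,
                "semi_minor_cm": nod.semi_minor_cm,
                "orientation_deg": nod.orientation_deg,
                "size_cm2": nod.size_cm2,
            }
        )
    columns = ["image_id", "nodule_id", "centroid_row", "centroid_col",
               "semi_major_cm", "semi_minor_cm", "orientation_deg", "size_cm2"]
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# Gridding


def _local_metric(records: list[ImageRecord]) -> tuple[float, float, float, float]:
    """Equirectangular local projection anchored at the min-lat/min-lon
    corner of the survey bounding box.  Returns (lat0, lon0, m_per_deg_lat,
    m_per_deg_lon); curvature is negligible at survey extents."""
    lats = [r.latitude for r in records]
    lons = [r.longitude for r in records]
    lat0, lon0 = min(lats), min(lons)
    m_per_deg_lat = math.pi / 180.0 * EARTH_RADIUS_M
    m_per_deg_lon = m_per_deg_lat * math.cos(math.radians(lat0))
    return lat0, lon0, m_per_deg_lat, m_per_deg_lon


_POOLED_FIELDS = ("phi_N", "phi_C", "trask_sorting", "trask_skewness")


def _pool(values: list[float], rule: str) -> float:
    vals = [v for v in values if not math.isnan(v)]
    if not vals:
        return float("nan")
    return max(vals) if rule == "max" else float(np.mean(vals))


def grid_aggregate(
    images: list[tuple[ImageRecord, list[Nodule]]],
    cell_m: float = 0.25,
    pooling: str = "max",
) -> list[GridCell]:
    """Aggregate per-image nodule lists onto a common geographic grid.

    Each image footprint (a ground rectangle centred on the image's
    lat/lon, axis-aligned with the grid) is tiled into ``cell_m`` cells;
    per cell and image, abundance statistics are computed from the nodules
    whose centroids fall inside the cell, over the cell area.  Cells
    covered by several images are pooled with ``pooling`` (``max``, the
    default, or ``mean``).  Images without coordinates are excluded with a
    warning entry in the module logger.
    """
    import logging

    log = logging.getLogger(__name__)
    if cell_m <= 0:
        raise ConfigurationError("cell_m must be positive")
    if pooling not in ("max", "mean"):
        raise ConfigurationError(f"pooling must be 'max' or 'mean', got {pooling!r}")
    usable = []
    for rec, nods in images:
        if rec.latitude is None or rec.longitude is None:
            log.warning("image %s has no coordinates; excluded from grid", rec.image_id)
            continue
        usable.append((rec, nods))
    if not usable:
        return []
    lat0, lon0, mlat, mlon = _local_metric([r for r, _ in usable])

    per_cell: dict[tuple[int, int], list[AbundanceStats]] = {}
    for rec, nods in usable:
        x_img = (rec.longitude - lon0) * mlon
        y_img = (rec.latitude - lat0) * mlat
        gw = rec.ground_width_m
        gh = rec.footprint_m2 / gw
        x0, x1 = x_img - gw / 2.0, x_img + gw / 2.0
        y0, y1 = y_img - gh / 2.0, y_img + gh / 2.0
        # Nodule ground positions (row grows southwards -> decreasing y);
        # centroid px refer to the raster the nodule was measured on, so
        # use each nodule's own px/cm resolution.
        nod_xy: list[tuple[float, float, Nodule]] = []
        for nod in nods:
            r, c = nod.centroid
            res = nod.resolution_px_per_cm
            nod_xy.append(
                (x0 + c / (100.0 * res), y1 - r / (100.0 * res), nod)
            )
        ci0, ci1 = int(math.floor(x0 / cell_m)), int(math.ceil(x1 / cell_m))
        cj0, cj1 = int(math.floor(y0 / cell_m)), int(math.ceil(y1 / cell_m))
        for ci in range(ci0, ci1):
            for cj in range(cj0, cj1):
                cell_nods = [
                    nod for (x, y, nod) in nod_xy
                    if ci * cell_m <= x < (ci + 1) * cell_m
                    and cj * cell_m <= y < (cj + 1) * cell_m
                ]
                stats = image_stats(cell_nods, cell_m**2)
                per_cell.setdefault((cj, ci), []).append(stats)

    cells: list[GridCell] = []
    for (cj, ci), stat_list in sorted(per_cell.items()):
        pooled = _pool_stats(stat_list, cell_m, pooling)
        lat = ((cj + 0.5) * cell_m) / mlat + lat0
        lon = ((ci + 0.5) * cell_m) / mlon + lon0
        cells.append(GridCell(cj, ci, lat, lon, pooled, len(stat_list)))
    return cells


def _pool_stats(stat_list: list[AbundanceStats], cell_m: float, rule: str) -> AbundanceStats:
    phi_s = {
        a: _pool([s.phi_S.get(a, float("nan")) for s in stat_list], rule)
        for a in SIZE_ALPHAS
    }
    n_pool = _pool([float(s.n_nodules) for s in stat_list], rule)
    return AbundanceStats(
        n_nodules=int(round(n_pool)) if not math.isnan(n_pool) else 0,
        phi_N=_pool([s.phi_N for s in stat_list], rule),
        phi_C=_pool([s.phi_C for s in stat_list], rule),
        phi_S=phi_s,
        trask_sorting=_pool([s.trask_sorting for s in stat_list], rule),
        trask_skewness=_pool([s.trask_skewness for s in stat_list], rule),
        area_m2=cell_m**2,
    )


def export_map(cells: list[GridCell], path, field_name: str = "phi_C") -> None:
    """Write the gridded map as (a) a long-format CSV and (b) a single-band
    ESRI ASCII-grid raster next to it.

    ``path`` is the CSV path; the raster gets the same stem with ``.asc``.
    NaN cells are encoded with the raster's NODATA value; the CSV keeps them
    as empty fields so the cell count is preserved.
    """
    from pathlib import Path

    if not cells:
        raise ConfigurationError("export_map: no cells")
    valid_fields = set(_POOLED_FIELDS) | {"n_nodules"} | {
        f"phi_S_{a:g}" for a in SIZE_ALPHAS
    }
    if field_name not in valid_fields:
        raise ConfigurationError(f"unknown field {field_name!r}")

    def get(cell: GridCell) -> float:
        row = cell.stats.as_row()
        return float(row[field_name])

    path = Path(path)
    rows = [
        {
            "cell_row": c.cell_row,
            "cell_col": c.cell_col,
            "lat": c.latitude,
            "lon": c.longitude,
            "value": get(c),
            "n_images": c.n_contributing_images,
        }
        for c in cells
    ]
    pd.DataFrame(rows).to_csv(path, index=False)

    # Raster: rows of the grid from north (max cell_row) to south.
    rmin = min(c.cell_row for c in cells)
    rmax = max(c.cell_row for c in cells)
    cmin = min(c.cell_col for c in cells)
    cmax = max(c.cell_col for c in cells)
    nrows, ncols = rmax - rmin + 1, cmax - cmin + 1
    grid = np.full((nrows, ncols), np.nan)
    for c in cells:
        grid[c.cell_row - rmin, c.cell_col - cmin] = get(c)
    nodata = -9999.0
    lines = [
        f"ncols {ncols}",
        f"nrows {nrows}",
        f"xllcorner {cmin}",
        f"yllcorner {rmin}",
        "cellsize 1",
        f"NODATA_value {nodata:g}",
    ]
    for r in range(nrows - 1, -1, -1):  # top row first (north)
        vals = np.where(np.isnan(grid[r]), nodata, grid[r])
        lines.append(" ".join(f"{v:.6g}" for v in vals))
    path.with_suffix(".asc").write_text("\n".join(lines) + "\n", encoding="utf-8")
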