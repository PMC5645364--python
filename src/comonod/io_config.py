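"""Survey metadata, camera geometry and run configuration.

A photo survey is described by a CSV table with one row per image
(``image_id``, ``path``, ``latitude``, ``longitude`` and either the seafloor
``footprint_m2`` imaged by the frame or the camera ``altitude`` in metres,
from which the footprint is derived through a pinhole ground-footprint
model).  The two algorithm parameters ``theta_gamma`` and ``theta_r`` plus
the gridding cell size live in :class:`RunConfig`.
"""

from __future__ import annotations

import json
import math
import statistics
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from PIL import Image

from .errors import ConfigurationError, RecordValidationError

__all__ = [
    "CameraModel",
    "ImageRecord",
    "RunConfig",
    "compute_footprint",
    "median_footprint",
    "read_survey_metadata",
    "write_survey_metadata",
]

#: α values of the characteristic size statistics Φ^s_α.
SIZE_ALPHAS = (0.01, 0.10, 0.25, 0.5, 0.75, 0.90, 0.99)


@dataclass(frozen=True)
class CameraModel:
    """Full opening angles of the (rectified) camera, in degrees."""

    fov_x_deg: float = 90.0
    fov_y_deg: float = 90.0

    def __post_init__(self) -> None:
        for v in (self.fov_x_deg, self.fov_y_deg):
            if not 0.0 < v < 180.0:
                raise ConfigurationError(
                    f"camera field of view must be in (0, 180) degrees, got {v}"
                )


@dataclass
class ImageRecord:
    """One survey image plus its geo-metadata.

    ``resolution_px_per_cm`` is derived from the footprint assuming the
    ground patch has the same aspect ratio as the pixel raster:
    ``ground_width_m = sqrt(footprint_m2 * width_px / height_px)`` and
    ``resolution = width_px / (100 * ground_width_m)``.
    """

    image_id: str
    path: Path
    latitude: float | None = None
    longitude: float | None = None
    altitude_m: float | None = None
    footprint_m2: float | None = None
    width_px: int | None = None
    height_px: int | None = None

    def __post_init__(self) -> None:
        self.path = Path(self.path)
        if self.footprint_m2 is not None and self.footprint_m2 <= 0:
            raise RecordValidationError(
                f"{self.image_id}: footprint_m2 must be positive, got {self.footprint_m2}"
            )
        if self.altitude_m is not None and self.altitude_m <= 0:
            raise RecordValidationError(
                f"{self.image_id}: altitude must be positive, got {self.altitude_m}"
            )
        if self.footprint_m2 is None and self.altitude_m is None:
            raise RecordValidationError(
                f"{self.image_id}: need footprint_m2 or altitude to determine the footprint"
            )
        for name in ("width_px", "height_px"):
            v = getattr(self, name)
            if v is not None and v < 16:
                raise RecordValidationError(
                    f"{self.image_id}: {name} must be >= 16, got {v}"
                )

    @property
    def ground_width_m(self) -> float:
        if self.footprint_m2 is None or not self.width_px or not self.height_px:
            raise RecordValidationError(
                f"{self.image_id}: footprint and pixel dimensions required"
            )
        aspect = self.width_px / self.height_px
        return math.sqrt(self.footprint_m2 * aspect)

    @property
    def resolution_px_per_cm(self) -> float:
        return self.width_px / (100.0 * self.ground_width_m)

    def with_footprint_from(self, camera: CameraModel) -> "ImageRecord":
        """Return a copy whose footprint is filled from altitude + camera."""
        if self.footprint_m2 is not None:
            return self
        fp = compute_footprint(self.altitude_m, camera)
        return replace(self, footprint_m2=fp)


@dataclass
class RunConfig:
    """Algorithm parameters for one processing run.

    theta_gamma
        Fraction of the compactness-derivative peak used as the cut-off
        when selecting the binarisation threshold, in (0, 1].
    theta_r
        Minimum expected object radius in pixels (>= 1).  Scales peak
        suppression (5*theta_r), blob fusion area (pi*theta_r**2) and
        fusion distance (2*theta_r).
    grid_cell_m
        Edge length of the abundance-map grid cell in metres.
    target_footprint_m2
        The common footprint A* the image set is rescaled to; the string
        ``"median-of-set"`` (default) takes the median footprint of the set.
    """

    theta_gamma: float = 0.10
    theta_r: int = 4
    grid_cell_m: float = 0.25
    target_footprint_m2: float | str = "median-of-set"
    seed: int = 0
    binarisation_polarity: str = "dark_objects"
    lowpass_fraction: float = 0.02
    derivative_smoothing: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.theta_gamma <= 1.0:
            raise ConfigurationError(
                f"theta_gamma must be in (0, 1], got {self.theta_gamma}"
            )
        if int(self.theta_r) != self.theta_r or self.theta_r < 1:
            raise ConfigurationError(
                f"theta_r must be a positive integer, got {self.theta_r}"
            )
        self.theta_r = int(self.theta_r)
        if self.grid_cell_m <= 0:
            raise ConfigurationError(
                f"grid_cell_m must be positive, got {self.grid_cell_m}"
            )
        if self.binarisation_polarity not in ("dark_objects", "bright_objects"):
            raise ConfigurationError(
                "binarisation_polarity must be 'dark_objects' or 'bright_objects', "
                f"got {self.binarisation_polarity!r}"
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a flat key/value config file (JSON, or YAML when available)."""
        text = Path(path).read_text(encoding="utf-8")
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            import yaml

            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: expected a flat key/value mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"{path}: unknown keys {sorted(unknown)}")
        return cls(**data)


def compute_footprint(altitude_m: float, camera: CameraModel) -> float:
    """Ground footprint in m² of a nadir frame from a flat-seafloor pinhole model.

    ``(2 h tan(fov_x/2)) * (2 h tan(fov_y/2))``, applied to already-rectified
    imagery.
    """
    if altitude_m is None or altitude_m <= 0:
        raise RecordValidationError(f"altitude must be positive, got {altitude_m}")
    gx = 2.0 * altitude_m * math.tan(math.radians(camera.fov_x_deg) / 2.0)
    gy = 2.0 * altitude_m * math.tan(math.radians(camera.fov_y_deg) / 2.0)
    return gx * gy


def median_footprint(records: Sequence[ImageRecord]) -> float:
    """Median footprint A* of the image set (mean of the two central values
    for even counts)."""
    if not records:
        raise ConfigurationError("median_footprint: empty record list")
    return float(statistics.median(r.footprint_m2 for r in records))


_REQUIRED_COLUMNS = ("image_id", "path")


def read_survey_metadata(
    csv_path: str | Path,
    camera: CameraModel | None = None,
    check_images: bool = False,
) -> tuple[list[ImageRecord], list[str]]:
    """Read a survey metadata CSV into :class:`ImageRecord` objects.

    Returns ``(records, problems)``: per-row validation failures (bad
    altitude, unreadable image file, ...) are reported in ``problems``
    as human-readable strings, never silently dropped.  A structurally
    broken table (missing required column) raises
    :class:`~comonod.errors.ConfigurationError`.

    When ``check_images`` is true, each image file is opened (header only)
    and its pixel dimensions recorded; otherwise ``width_px``/``height_px``
    CSV columns are used when present.
    """
    df = pd.read_csv(csv_path)
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ConfigurationError(f"{csv_path}: missing required column '{col}'")
    if "footprint_m2" not in df.columns and "altitude" not in df.columns:
        raise ConfigurationError(
            f"{csv_path}: need a 'footprint_m2' or 'altitude' column"
        )

    records: list[ImageRecord] = []
    problems: list[str] = []
    for idx, row in df.iterrows():
        if pd.isna(row["path"]) or str(row["path"]).strip() == "":
            problems.append(f"row {idx}: missing 'path'")
            continue
        try:
            rec = ImageRecord(
                image_id=str(row["image_id"]),
                path=Path(str(row["path"])),
                latitude=_opt_float(row, "latitude"),
                longitude=_opt_float(row, "longitude"),
                altitude_m=_opt_float(row, "altitude"),
                footprint_m2=_opt_float(row, "footprint_m2"),
                width_px=_opt_int(row, "width_px"),
                height_px=_opt_int(row, "height_px"),
            )
            if rec.footprint_m2 is None:
                if camera is None:
                    raise RecordValidationError(
                        f"{rec.image_id}: footprint absent and no camera model given"
                    )
                rec = rec.with_footprint_from(camera)
            if check_images:
                try:
                    with Image.open(rec.path) as im:
                        rec.width_px, rec.height_px = im.size
                except (OSError, ValueError) as exc:
                    raise RecordValidationError(
                        f"{rec.image_id}: unreadable image file {rec.path} ({exc})"
                    ) from exc
        except RecordValidationError as exc:
            problems.append(f"row {idx}: {exc}")
            continue
        records.append(rec)
    return records, problems


def write_survey_metadata(records: Iterable[ImageRecord], csv_path: str | Path) -> None:
    """Write records back to CSV (round-trips with :func:`read_survey_metadata`)."""
    rows = []
    for r in records:
        rows.append(
            {
                "image_id": r.image_id,
                "path": str(r.path),
                "latitude": r.latitude,
                "longitude": r.longitude,
                "altitude": r.altitude_m,
                "footprint_m2": r.footprint_m2,
                "width_px": r.width_px,
                "height_px": r.height_px,
            }
        )
    pd.DataFrame(rows).to_csv(csv_path, index=False, float_format="%.12g")


def _opt_float(row: pd.Series, key: str) -> float | None:
    if key not in row or pd.isna(row[key]):
        return None
    return float(row[key])


def _opt_int(row: pd.Series, key: str) -> int | None:
    v = _opt_float(row, key)
    return None if v is None else int(v)
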