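"""Image and tabular I/O for exine morphometrics.

SEM surface crops are read into float arrays in [0, 1]; grain metadata and
feature tables move through plain CSV so that every intermediate of a run can
be inspected and re-read without loss.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Spatio-temporal group labels used throughout: Early-to-Middle-Miocene
#: fossils, Late-Miocene-to-Pleistocene fossils, and extant material.
VALID_GROUPS = frozenset(
    {"G1_early_mid_miocene", "G2_late_miocene_pleistocene", "G3_extant"}
)

#: Canonical order of the 40 feature columns: log size, log density, then the
#: 19 SC2 and 19 SC3 expanding-region component counts.
FEATURE_COLUMNS: tuple[str, ...] = (
    ("log_size", "log_density")
    + tuple(f"sc2_{k:02d}" for k in range(1, 20))
    + tuple(f"sc3_{k:02d}" for k in range(1, 20))
)

#: Pixel pitch of a 1855-px crop spanning 3.3 um^2 at x150 000 magnification.
DEFAULT_PIXEL_SIZE_NM = 0.98

MIN_IMAGE_PX = 120
MIN_ANALYSIS_PX = 1000


@dataclass
class GrayscaleImage:
    """A 2-D grayscale intensity grid with optional physical pixel size.

    Parameters
    ----------
    pixels
        2-D float array with values in [0, 1].
    pixel_size_nm
        Edge length of one pixel in nanometres, if known (~0.98 nm for the
        nominal x150 000 SEM crops).
    """

    pixels: np.ndarray
    pixel_size_nm: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D image, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite intensities")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise ValueError("intensities must lie in [0, 1]")
        if min(self.pixels.shape) < MIN_IMAGE_PX:
            raise ValueError(
                f"image {self.pixels.shape} smaller than {MIN_IMAGE_PX} px minimum"
            )
        if self.pixel_size_nm is not None and self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class GrainRecord:
    """Metadata for one pollen grain: identity, provenance and image path."""

    grain_id: str
    image_path: str
    group: str
    sample_id: str = ""
    subfamily: str | None = None
    age_ma: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise ValueError(
                f"unknown group {self.group!r} for grain {self.grain_id!r}; "
                f"expected one of {sorted(VALID_GROUPS)}"
            )
        if self.age_ma is not None and self.age_ma < 0:
            raise ValueError(f"negative age_ma for grain {self.grain_id!r}")


def load_image(
    path: str | Path,
    *,
    pixel_size_nm: float | None = None,
    min_size: int = MIN_ANALYSIS_PX,
) -> GrayscaleImage:
    """Read a TIFF/PNG crop into a [0, 1] grayscale image.

    Intensities are divided by the dtype maximum (255 or 65535), not the
    image's own maximum, so absolute brightness stays comparable across
    grains.  RGB inputs are collapsed to luminance with a warning.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except Exception as exc:  # plugin backends raise assorted types
        raise OSError(f"cannot read image file {path}: {exc}") from exc
    if raw.ndim == 3:
        warnings.warn(
            f"{path.name}: color image converted to grayscale by luminance",
            stacklevel=2,
        )
        rgb = raw[..., :3].astype(np.float64)
        raw_f = rgb @ np.array([0.2126, 0.7152, 0.0722])
    else:
        raw_f = raw.astype(np.float64)

    if np.issubdtype(raw.dtype, np.integer):
        denom = float(np.iinfo(raw.dtype).max)
    else:
        denom = 1.0
    pixels = np.clip(raw_f / denom, 0.0, 1.0)
    if min(pixels.shape) < min_size:
        raise ValueError(
            f"{path.name}: image {pixels.shape} below the {min_size} px "
            "analysis minimum"
        )
    return GrayscaleImage(pixels, pixel_size_nm=pixel_size_nm)


def save_image(image: GrayscaleImage | np.ndarray, path: str | Path) -> None:
    """Write an image as 16-bit grayscale PNG/TIFF (lossless to ~1/65535)."""
    pixels = image.pixels if isinstance(image, GrayscaleImage) else np.asarray(image)
    data = np.round(np.clip(pixels, 0.0, 1.0) * 65535).astype(np.uint16)
    iio.imwrite(Path(path), data)


def load_metadata(
    path: str | Path,
    *,
    check_images: bool = True,
    min_image_size: int = MIN_ANALYSIS_PX,
) -> list[GrainRecord]:
    """Read and validate the grain metadata CSV.

    Required columns: ``grain_id``, ``image_path``, ``group``.  Optional
    columns ``sample_id``, ``subfamily``, ``age_ma`` are mapped onto the
    record; any further columns are carried in ``extra``.  Relative image
    paths resolve against the CSV's directory.  Missing image files are
    rejected here rather than mid-pipeline.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"grain_id": str})
    required = {"grain_id", "image_path", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata {path} missing required columns {sorted(missing)}")
    dupes = df["grain_id"][df["grain_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate grain_id values in {path}: {sorted(set(dupes))}")

    known = {"grain_id", "image_path", "group", "sample_id", "subfamily", "age_ma"}
    records: list[GrainRecord] = []
    for row in df.to_dict("records"):
        img = Path(str(row["image_path"]))
        if not img.is_absolute():
            img = path.parent / img
        rec = GrainRecord(
            grain_id=str(row["grain_id"]),
            image_path=str(img),
            group=str(row["group"]),
            sample_id=str(row.get("sample_id", "") or ""),
            subfamily=_opt_str(row.get("subfamily")),
            age_ma=_opt_float(row.get("age_ma")),
            extra={k: row[k] for k in df.columns if k not in known},
        )
        if check_images:
            if not img.exists():
                raise FileNotFoundError(
                    f"image for grain {rec.grain_id!r} not found: {img}"
                )
            try:
                shape = iio.improps(img).shape
            except Exception:
                shape = None  # unreadable files surface when extracted
            if shape is not None and min(shape[:2]) < min_image_size:
                raise ValueError(
                    f"image for grain {rec.grain_id!r} is {shape[:2]}, below "
                    f"the {min_image_size} px analysis minimum: {img}"
                )
        records.append(rec)
    logger.info("loaded %d grain records from %s", len(records), path)
    return records


def _opt_str(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value)
    return s if s else None


def _opt_float(value) -> float | None:
    if value is None:
        return None
    try:
        f = float(value)
    except (TypeError, ValueError):
        return None
    return None if np.isnan(f) else f


METADATA_COLUMNS = ("grain_id", "sample_id", "group", "subfamily", "age_ma")


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table as CSV with the canonical column order.

    Columns: grain_id, sample_id, group, subfamily, age_ma, then the 40
    features; extra metadata columns follow.  Values are written with 17
    significant digits so a round-trip is lossless at double precision.
    Rows with missing feature values are refused.
    """
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns {missing}")
    if len(table) == 0:
        warnings.warn("writing an empty feature table (header only)", stacklevel=2)
    elif table[list(FEATURE_COLUMNS)].isna().any().any():
        bad = table.loc[
            table[list(FEATURE_COLUMNS)].isna().any(axis=1), "grain_id"
        ].tolist()
        raise ValueError(f"partial feature rows refused for grains {bad}")
    lead = [c for c in METADATA_COLUMNS if c in table.columns]
    rest = [c for c in table.columns if c not in lead and c not in FEATURE_COLUMNS]
    ordered = table[lead + list(FEATURE_COLUMNS) + rest]
    ordered.to_csv(Path(path), index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a features CSV, checking the 40-column schema is present."""
    df = pd.read_csv(Path(path), dtype={"grain_id": str})
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: not a feature table, missing {missing}")
    return df


def write_manifest(path: str | Path, *, seed: int, config: dict) -> None:
    """Record run provenance (seed, config, config hash, version) as JSON."""
    import hashlib

    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "version": __version__,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
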