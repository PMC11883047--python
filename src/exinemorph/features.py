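"""Grain-level 40-D feature vectors and study feature tables.

Per analysis window the pipeline measures size, density, and the SC2/SC3
count families; per grain those are averaged over the windows (mean first,
then the log transform of mean size and mean density) into the canonical
40-feature vector: ``log_size, log_density, sc2_01..sc2_19, sc3_01..sc3_19``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .centrality import sc_feature_vector
from .config import PipelineConfig
from .io import FEATURE_COLUMNS, GrainRecord, GrayscaleImage, load_image
from .ornament import density_feature, size_feature
from .preprocess import SubImageSet, derive_seed, equalize_contrast, sample_subimages

logger = logging.getLogger(__name__)


class IncompleteGrainError(ValueError):
    """No window of the grain yielded a usable measurement."""


@dataclass
class FeatureVector:
    """The 40 grain-level features in canonical order."""

    log_size: float
    log_density: float
    sc2: np.ndarray
    sc3: np.ndarray

    def to_array(self) -> np.ndarray:
        vec = np.concatenate(
            [[self.log_size, self.log_density], self.sc2, self.sc3]
        )
        if vec.shape != (40,):
            raise ValueError(f"feature vector has length {vec.size}, expected 40")
        return vec

    def to_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_COLUMNS, self.to_array()))


def grain_features(
    subset: SubImageSet, config: PipelineConfig | None = None
) -> FeatureVector:
    """Aggregate one grain's windows into its 40-D feature vector.

    Size and density are averaged over the windows that produced a valid
    measurement and then logged (mean-then-log); windows with no detected
    object are skipped for size.  A grain where every window fails is
    incomplete and raises :class:`IncompleteGrainError`.
    """
    cfg = config or PipelineConfig()
    sizes, densities, sc2s, sc3s = [], [], [], []
    for window in subset.windows:
        s = size_feature(
            window,
            min_area_px=cfg.min_area_px,
            edge_threshold=cfg.edge_threshold,
            edge_sigma=cfg.edge_sigma,
        )
        if np.isfinite(s):
            sizes.append(s)
        densities.append(
            density_feature(
                window,
                k=cfg.density_kmeans_k,
                closing_radius_px=cfg.closing_radius_px,
                min_area_px=cfg.min_area_px,
                quantize_sigma=cfg.density_quantize_sigma,
            )
        )
        scv = sc_feature_vector(
            window,
            resize_to=cfg.sc_resize_to,
            crop_to=cfg.sc_crop_to,
            grid=cfg.sc_grid,
            steps=cfg.sc_steps,
            step_fraction=cfg.sc_step_fraction,
            boundary_weight=cfg.sc_boundary_weight,
            interior_weight=cfg.sc_interior_weight,
            kmeans_k=cfg.kmeans_k,
        )
        sc2s.append(scv.sc2)
        sc3s.append(scv.sc3)

    if not sizes:
        raise IncompleteGrainError(
            f"grain {subset.parent_grain_id!r}: no window yielded a size measurement"
        )
    mean_density = float(np.mean(densities))
    if mean_density <= 0:
        raise IncompleteGrainError(
            f"grain {subset.parent_grain_id!r}: zero mean density, cannot log"
        )
    log = np.log if cfg.log_base == "e" else np.log10
    return FeatureVector(
        log_size=float(log(np.mean(sizes))),
        log_density=float(log(mean_density)),
        sc2=np.mean(sc2s, axis=0),
        sc3=np.mean(sc3s, axis=0),
    )


def extract_grain(
    record: GrainRecord, config: PipelineConfig | None = None
) -> FeatureVector:
    """Load, equalize, sample and measure one grain end to end."""
    cfg = config or PipelineConfig()
    image = load_image(record.image_path, min_size=cfg.window_px)
    return extract_from_image(image, record.grain_id, cfg)


def extract_from_image(
    image: GrayscaleImage, grain_id: str, config: PipelineConfig | None = None
) -> FeatureVector:
    """Feature vector of an in-memory crop (equalize, sample, measure)."""
    cfg = config or PipelineConfig()
    equalized = equalize_contrast(
        image,
        tile_grid=cfg.tile_grid,
        clip_limit=cfg.clip_limit,
        rayleigh_sigma=cfg.rayleigh_sigma,
    )
    subset = sample_subimages(
        equalized,
        n=cfg.n_subimages,
        size=cfg.window_px,
        seed=derive_seed(cfg.seed, grain_id),
        parent_grain_id=grain_id,
    )
    return grain_features(subset, cfg)


def build_feature_table(
    records: list[GrainRecord], vectors: dict[str, FeatureVector]
) -> pd.DataFrame:
    """Join grain metadata with feature vectors into the study table.

    ``vectors`` maps grain_id -> FeatureVector for the completed grains;
    records without a vector are excluded (their ids are logged).  A vector
    without a matching record is an error.
    """
    ids = {r.grain_id for r in records}
    orphans = set(vectors) - ids
    if orphans:
        raise ValueError(f"feature vectors without metadata records: {sorted(orphans)}")
    excluded = [r.grain_id for r in records if r.grain_id not in vectors]
    if excluded:
        logger.info("excluding %d incomplete grains: %s", len(excluded), excluded)
    rows = []
    for rec in records:
        if rec.grain_id not in vectors:
            continue
        row = {
            "grain_id": rec.grain_id,
            "sample_id": rec.sample_id,
            "group": rec.group,
            "subfamily": rec.subfamily,
            "age_ma": rec.age_ma,
            **rec.extra,
            **vectors[rec.grain_id].to_dict(),
        }
        rows.append(row)
    columns = ["grain_id", "sample_id", "group", "subfamily", "age_ma"]
    extra_cols = [c for c in (rows[0] if rows else {}) if c not in columns + list(FEATURE_COLUMNS)]
    return pd.DataFrame(rows, columns=columns + list(FEATURE_COLUMNS) + extra_cols)


def extract_cohort(
    records: list[GrainRecord], config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Extract features for a whole cohort, skipping failed grains with a log."""
    cfg = config or PipelineConfig()
    vectors: dict[str, FeatureVector] = {}
    for rec in records:
        try:
            vectors[rec.grain_id] = extract_grain(rec, cfg)
        except (IncompleteGrainError, OSError, ValueError) as exc:
            logger.warning("skipping grain %s: %s", rec.grain_id, exc)
    if not vectors:
        raise RuntimeError("feature extraction failed for every grain")
    return build_feature_table(records, vectors)
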