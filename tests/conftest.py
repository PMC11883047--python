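"""Shared fixtures: small synthetic images and the session study cohort.

The expensive fixture (three-group cohort, features extracted at reduced
512-px frames) is session-scoped and shared by the parameter-recovery and
morphospace-shift tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import exinemorph as em
from exinemorph.config import PipelineConfig
from exinemorph.features import extract_from_image

COHORT_SEED = 20240


def disc_image(
    shape: tuple[int, int] = (200, 200),
    center: tuple[float, float] = (100.0, 100.0),
    radius: float = 20.0,
    background: float = 0.2,
    level: float = 0.9,
) -> np.ndarray:
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    img = np.full(shape, background)
    img[(yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2] = level
    return img


@pytest.fixture(scope="session")
def reduced_config() -> PipelineConfig:
    return PipelineConfig(window_px=256, seed=COHORT_SEED)


def _extract_cohort(spec, out, config):
    records, params_log = em.generate_cohort(spec, out)
    vectors = {}
    for rec in records:
        image = em.load_image(rec.image_path, min_size=config.window_px)
        vectors[rec.grain_id] = extract_from_image(image, rec.grain_id, config)
    table = em.build_feature_table(records, vectors)
    return {"records": records, "params_log": params_log, "table": table, "dir": out}


@pytest.fixture(scope="session")
def study_cohort(tmp_path_factory, reduced_config):
    """Three-group scenario cohort (10 grains each, 512-px frames, density
    means 60/40/25) with its extracted feature table and parameter log."""
    out = tmp_path_factory.mktemp("cohort")
    spec = em.study_cohort_spec(seed=COHORT_SEED, n_per_group=10)
    return _extract_cohort(spec, out, reduced_config)


@pytest.fixture(scope="session")
def recovery_cohort(tmp_path_factory, reduced_config):
    """Parameter-recovery cohort: 30 grains spanning counts 20-80 and radii
    14-22 px on independent shuffled grids."""
    out = tmp_path_factory.mktemp("recovery")
    spec = em.recovery_set_spec(seed=COHORT_SEED + 1, n_grains=30)
    return _extract_cohort(spec, out, reduced_config)


@pytest.fixture(scope="session")
def cohort_merged(recovery_cohort) -> pd.DataFrame:
    return recovery_cohort["table"].merge(
        recovery_cohort["params_log"][
            ["grain_id", "element_count", "element_radius_px"]
        ],
        on="grain_id",
    )
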