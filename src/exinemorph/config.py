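"""Run configuration: every tunable of the pipeline in one serializable place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Parameters of the feature-extraction pipeline.

    The defaults reproduce the nominal protocol for 1855 x 1855 crops at
    x150 000 magnification; for smaller synthetic frames set ``window_px``
    (and the generator radii) proportionally.
    """

    # preprocessing
    tile_grid: tuple[int, int] = (8, 8)
    clip_limit: float = 0.01
    rayleigh_sigma: float = 0.4
    n_subimages: int = 5
    window_px: int = 1000

    # ornament features
    kmeans_k: int = 4  # SC quantization depth (protocol-fixed)
    density_kmeans_k: int = 3  # density foreground quantization depth
    density_quantize_sigma: float = 1.0  # pre-quantization smoothing (px)
    closing_radius_px: int = 2
    min_area_px: int = 5
    edge_threshold: float | str = "otsu"
    edge_sigma: float = 1.0

    # subgraph-centrality features
    sc_resize_to: int = 200
    sc_crop_to: int = 120
    sc_grid: int = 40
    sc_steps: int = 19
    sc_step_fraction: float = 0.05
    sc_boundary_weight: float = 0.01
    sc_interior_weight: float = 1.0

    # assembly
    log_base: str = "e"  # "e" or "10"

    # run
    seed: int = 0
    group_col: str = "group"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if isinstance(cfg.tile_grid, list):
            cfg.tile_grid = tuple(cfg.tile_grid)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def __post_init__(self) -> None:
        if self.log_base not in ("e", "10"):
            raise ValueError("log_base must be 'e' or '10'")
        if self.sc_crop_to % self.sc_grid:
            raise ValueError("sc_crop_to must be divisible by sc_grid")
        if self.n_subimages < 1:
            raise ValueError("n_subimages must be >= 1")
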