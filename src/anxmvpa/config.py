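"""Validated pipeline configuration (YAML-serializable, unknown keys rejected)."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .synthetic_data import CohortSpec


class CohortConfig(BaseModel):
    """Synthetic cohort parameters — mirrors :class:`CohortSpec` defaults."""

    model_config = ConfigDict(extra="forbid")

    n_anxious: int = 22
    n_control: int = 23
    atlas_shape: tuple[int, int, int] = (12, 12, 12)
    n_regions: int = 20
    voxels_per_region: int = 40
    T: int = 35
    signal_region_id: int = 7
    group_effect: float = 2.0
    stim_effect: float = 2.0
    k_shared: int = 3
    noise_sd: float = 1.0
    coupled_region_ids: tuple[int, ...] = ()
    coupling: float = 0.5
    design: str = "compact"

    def to_spec(self, seed: int) -> CohortSpec:
        spec = CohortSpec(seed=seed, **self.model_dump())
        spec.validate()
        return spec


class PipelineConfig(BaseModel):
    """End-to-end pipeline settings with a strict schema."""

    model_config = ConfigDict(extra="forbid")

    data_dir: str | None = None  # read an existing cohort instead of simulating
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    seed: int = 0
    out_dir: str = "results"
    reduced_grid: bool = True  # one-point grid; False runs the full printed grid
    srm_k: int = 10
    stimulus_folds: int = 5
    outer_folds: int = 5
    inner_folds: int = 5
    connectome_threshold: float = 0.6
    hrf_lag_seconds: float = 4.0
    verbosity: str = "info"


def load_config(path: str | Path | None, **overrides) -> PipelineConfig:
    """Load a YAML config (or defaults) and apply flag overrides."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**raw)
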