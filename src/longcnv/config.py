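"""Structured pipeline configuration.

A single YAML file with nested sections mirroring the simulator and
segmentation parameter sets; unknown keys are rejected and every field has
a default, so an empty config runs the default synthetic cohort end to end.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .segmentation import SegmentationParams
from .sim import SimConfig

__all__ = ["PipelineConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimSection(_Strict):
    n_subjects: int = 8
    n_timepoints: int = 3
    n_chromosomes: int = 10
    markers_per_chromosome: int = 120
    mean_spacing_bp: int = 50_000
    noise_sd: float = 0.15
    loss_shift: float = -0.6
    gain_shift: float = 0.45
    class_counts: dict[str, int] = Field(
        default_factory=lambda: {"constant": 14, "de_novo_23": 5, "de_novo_3": 8}
    )
    gain_fraction: float = 0.1
    cnv_markers_min: int = 5
    cnv_markers_max: int = 10
    min_gap_markers: int = 10
    gc_wave_amplitude: float = 0.0
    gc_wave_period_markers: int = 500
    outlier_rate: float = 0.0
    seed: int = 0

    def to_sim_config(self) -> SimConfig:
        return SimConfig(**self.model_dump())


class SegmentationSection(_Strict):
    max_pairwise_p: float = 0.005
    min_markers: int = 2
    loss_threshold: float = -0.35
    gain_threshold: float = 0.35
    outlier_removal: bool = True
    outlier_mad_k: float = 3.0
    outlier_window: int = 5

    def to_params(self) -> SegmentationParams:
        return SegmentationParams(**self.model_dump())


class MatchingSection(_Strict):
    min_reciprocal_overlap: float = 0.5

    @field_validator("min_reciprocal_overlap")
    @classmethod
    def _check_fraction(cls, v: float) -> float:
        if not 0 < v <= 1:
            raise ValueError("min_reciprocal_overlap must be in (0, 1]")
        return v


class EnrichmentSection(_Strict):
    reference_size: int = 19_639
    min_overlap_bp: int = 1


class PathsSection(_Strict):
    """Optional real-data inputs; when unset the synthetic cohort is used."""

    logr_tsv: str | None = None
    final_report: str | None = None
    genes: str | None = None
    qtls: str | None = None
    gmt: str | None = None


class PipelineConfig(_Strict):
    sim: SimSection = Field(default_factory=SimSection)
    segmentation: SegmentationSection = Field(default_factory=SegmentationSection)
    matching: MatchingSection = Field(default_factory=MatchingSection)
    enrichment: EnrichmentSection = Field(default_factory=EnrichmentSection)
    paths: PathsSection = Field(default_factory=PathsSection)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML config; a missing path yields the defaults."""
    if path is None:
        return PipelineConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig.model_validate(data)
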