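"""Synthetic logR cohorts with planted CNVs.

Emulates a 50k-density autosomal SNP-array experiment sampled at three time
points per subject: an ordered marker map, a set of planted copy-number
segments whose presence across time points follows the constant / de novo /
inconsistent classes, and per-sample logR tracks built as baseline 0 plus
Gaussian noise, optional long-period "genomic wave" and single-marker
outlier spikes.

Everything is deterministic for a fixed :class:`SimConfig` (one master seed;
per-sample noise streams are derived from it).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "MarkerMap",
    "TruthCnv",
    "PATTERN_BY_CLASS",
    "make_marker_map",
    "plant_truth",
    "render_logr",
    "simulate_cohort",
    "sample_name",
]

#: presence patterns (t1, t2, t3) for each temporal class used when planting
PATTERN_BY_CLASS: dict[str, tuple[tuple[bool, bool, bool], ...]] = {
    "constant": ((True, True, True),),
    "de_novo_23": ((False, True, True),),
    "de_novo_3": ((False, False, True),),
    "inconsistent": ((True, False, False), (False, True, False), (True, True, False)),
}


class SimulationError(ValueError):
    """Requested truth set does not fit on the marker map."""


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic cohort.

    Shifts default to -0.6 (one-copy loss) and +0.45 (one-copy gain), typical
    Illumina logR magnitudes that clear the +/-0.35 segment-mean filter with
    margin at the default noise level.
    """

    n_subjects: int = 8
    n_timepoints: int = 3
    n_chromosomes: int = 10
    markers_per_chromosome: int = 120
    mean_spacing_bp: int = 50_000
    noise_sd: float = 0.15
    loss_shift: float = -0.6
    gain_shift: float = 0.45
    #: planted trajectories per subject, keyed by temporal class
    class_counts: Mapping[str, int] = field(
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

    def __post_init__(self) -> None:
        if self.n_chromosomes <= 0 or self.markers_per_chromosome <= 0:
            raise ConfigError("marker and chromosome counts must be positive")
        if self.n_subjects <= 0 or self.n_timepoints <= 0:
            raise ConfigError("n_subjects and n_timepoints must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ConfigError("outlier_rate must be in [0, 1]")
        if any(v < 0 for v in self.class_counts.values()):
            raise ConfigError("class counts must be >= 0")
        unknown = set(self.class_counts) - set(PATTERN_BY_CLASS)
        if unknown:
            raise ConfigError(f"unknown temporal classes: {sorted(unknown)}")
        if not self.cnv_markers_min <= self.cnv_markers_max:
            raise ConfigError("cnv_markers_min must be <= cnv_markers_max")
        if self.cnv_markers_min < 1:
            raise ConfigError("cnv_markers_min must be >= 1")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class MarkerMap:
    """Ordered autosomal marker coordinates.

    ``df`` has columns ``chromosome`` (str), ``position`` (int, 1-based) and
    ``marker_id``, sorted by (chromosome order of appearance, position), with
    a default RangeIndex. All signal arrays are aligned to these rows.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chromosome", "position", "marker_id"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"marker map missing columns: {sorted(missing)}")

    @property
    def n_markers(self) -> int:
        return len(self.df)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.df["chromosome"]))

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous row ranges per chromosome, in map order."""
        out: dict[str, slice] = {}
        chroms = self.df["chromosome"].to_numpy()
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out[chroms[start]] = slice(start, i)
                start = i
        return out

    def positions(self) -> np.ndarray:
        return self.df["position"].to_numpy()


@dataclass(frozen=True)
class TruthCnv:
    """One planted CNV of one subject (marker indices are global map rows,
    inclusive on both ends)."""

    subject_id: str
    chromosome: str
    start_marker_index: int
    end_marker_index: int
    state: str  # "loss" | "gain"
    mean_shift: float
    presence_pattern: tuple[bool, ...]

    def __post_init__(self) -> None:
        if self.end_marker_index < self.start_marker_index:
            raise ValueError("end marker before start marker")
        if self.mean_shift == 0:
            raise ValueError("mean_shift must be non-zero")
        if not any(self.presence_pattern):
            raise ValueError("presence pattern must have at least one true entry")

    @property
    def n_markers(self) -> int:
        return self.end_marker_index - self.start_marker_index + 1


def sample_name(subject_id: str, time_point: int) -> str:
    """Column label for one subject x time-point track (time points 1-based)."""
    return f"{subject_id}_t{time_point}"


def make_marker_map(config: SimConfig) -> MarkerMap:
    """Draw an ordered autosomal marker map.

    Inter-marker spacing is uniform on [0.5, 1.5] x ``mean_spacing_bp`` so the
    mean spacing matches the requested array density while positions stay
    strictly increasing within each chromosome.
    """
    rng = np.random.default_rng([config.seed, 0xA11])
    records = []
    for c in range(config.n_chromosomes):
        chrom = str(c + 1)
        spacing = rng.uniform(
            0.5 * config.mean_spacing_bp,
            1.5 * config.mean_spacing_bp,
            size=config.markers_per_chromosome,
        ).astype(np.int64)
        spacing = np.maximum(spacing, 1)
        pos = np.cumsum(spacing)
        for j, p in enumerate(pos):
            records.append((chrom, int(p), f"SNP_{chrom}_{j + 1}"))
    df = pd.DataFrame(records, columns=["chromosome", "position", "marker_id"])
    return MarkerMap(df)


def plant_truth(config: SimConfig, marker_map: MarkerMap) -> list[TruthCnv]:
    """Place non-overlapping truth CNVs for every subject.

    The genomic layout (positions, lengths, states, patterns) is drawn once
    from the master seed and replicated across subjects, so truth lists are
    identical up to ``subject_id``.
    """
    rng = np.random.default_rng([config.seed, 0x7E0])
    patterns: list[tuple[bool, ...]] = []
    for cls in sorted(config.class_counts):
        pool = PATTERN_BY_CLASS[cls]
        for i in range(config.class_counts[cls]):
            patterns.append(pool[i % len(pool)])
    if not patterns:
        return []
    rng.shuffle(patterns)  # interleave classes along the genome

    n_cnvs = len(patterns)
    lengths = rng.integers(
        config.cnv_markers_min, config.cnv_markers_max + 1, size=n_cnvs
    )
    is_gain = rng.random(n_cnvs) < config.gain_fraction

    # Sequential placement: walk the chromosomes leaving >= min_gap_markers
    # between consecutive CNVs and at chromosome edges.
    slices = marker_map.chrom_slices()
    layout: list[tuple[str, int, int]] = []
    chrom_iter = iter(slices.items())
    chrom, sl = next(chrom_iter)
    cursor = sl.start + config.min_gap_markers
    for L in lengths:
        while True:
            if cursor + int(L) + config.min_gap_markers <= sl.stop:
                layout.append((chrom, cursor, cursor + int(L) - 1))
                cursor += int(L) + config.min_gap_markers
                break
            try:
                chrom, sl = next(chrom_iter)
            except StopIteration:
                raise SimulationError(
                    f"marker map too small for {n_cnvs} CNVs of up to "
                    f"{config.cnv_markers_max} markers per subject"
                ) from None
            cursor = sl.start + config.min_gap_markers

    truth: list[TruthCnv] = []
    for s in range(config.n_subjects):
        subject = f"S{s + 1}"
        for (chrom, lo, hi), pattern, gain in zip(layout, patterns, is_gain):
            truth.append(
                TruthCnv(
                    subject_id=subject,
                    chromosome=chrom,
                    start_marker_index=lo,
                    end_marker_index=hi,
                    state="gain" if gain else "loss",
                    mean_shift=config.gain_shift if gain else config.loss_shift,
                    presence_pattern=tuple(pattern[: config.n_timepoints]),
                )
            )
    return truth


def render_logr(
    truth: Sequence[TruthCnv], marker_map: MarkerMap, config: SimConfig
) -> pd.DataFrame:
    """Render the marker x sample logR matrix.

    Columns are ``<subject>_t<k>``; each track is baseline 0 plus iid Gaussian
    noise, plus the planted shifts at time points where the CNV is present,
    plus the optional wave and outlier spikes.
    """
    n = marker_map.n_markers
    idx = np.arange(n)
    wave = config.gc_wave_amplitude * np.sin(
        2 * np.pi * idx / config.gc_wave_period_markers
    )
    by_subject: dict[str, list[TruthCnv]] = {}
    for t in truth:
        by_subject.setdefault(t.subject_id, []).append(t)

    cols: dict[str, np.ndarray] = {}
    for s in range(config.n_subjects):
        subject = f"S{s + 1}"
        for tp in range(1, config.n_timepoints + 1):
            rng = np.random.default_rng([config.seed, 0x5D, s, tp])
            track = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 else np.zeros(n)
            track = track + wave
            if config.outlier_rate > 0:
                spikes = rng.random(n) < config.outlier_rate
                signs = rng.choice([-1.0, 1.0], size=n)
                track = track + np.where(spikes, signs, 0.0)
            for cnv in by_subject.get(subject, []):
                if cnv.presence_pattern[tp - 1]:
                    track[cnv.start_marker_index : cnv.end_marker_index + 1] += cnv.mean_shift
            cols[sample_name(subject, tp)] = track
    return pd.DataFrame(cols)


def wave_covariate(marker_map: MarkerMap, config: SimConfig) -> np.ndarray:
    """The sinusoidal composition covariate used by the wave generator
    (unit amplitude), for use as the QC wave-metric covariate."""
    idx = np.arange(marker_map.n_markers)
    return np.sin(2 * np.pi * idx / config.gc_wave_period_markers)


def simulate_cohort(
    config: SimConfig,
) -> tuple[MarkerMap, list[TruthCnv], pd.DataFrame]:
    """Map + truth + logR matrix in one call."""
    marker_map = make_marker_map(config)
    truth = plant_truth(config, marker_map)
    tracks = render_logr(truth, marker_map, config)
    return marker_map, truth, tracks
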