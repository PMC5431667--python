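import numpy as np
import pandas as pd
import pytest

from longcnv.segmentation import SegmentationParams
from longcnv.sim import MarkerMap, SimConfig, simulate_cohort


def make_map(n_markers: int, chrom: str = "1", spacing: int = 50_000) -> MarkerMap:
    """Uniformly spaced single-chromosome map for unit tests."""
    return MarkerMap(
        pd.DataFrame(
            {
                "chromosome": [chrom] * n_markers,
                "position": np.arange(1, n_markers + 1) * spacing,
                "marker_id": [f"m{i}" for i in range(n_markers)],
            }
        )
    )


@pytest.fixture
def flat_map():
    return make_map(60)


@pytest.fixture
def default_params():
    return SegmentationParams()


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully featured cohort: 2 subjects, all four temporal
    classes planted, default noise."""
    cfg = SimConfig(
        n_subjects=2,
        n_chromosomes=4,
        markers_per_chromosome=120,
        class_counts={"constant": 4, "de_novo_23": 2, "de_novo_3": 2, "inconsistent": 2},
        seed=11,
    )
    marker_map, truth, tracks = simulate_cohort(cfg)
    return cfg, marker_map, truth, tracks
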