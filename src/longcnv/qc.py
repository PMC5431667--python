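"""Sample-level quality control for logR tracks.

Four screens mirror standard SNP-array practice: (1) exclusion of sex
chromosomes before any autosomal CNV work, (2) derivative log ratio spread
(dLRS) as a per-sample noise metric, with Tukey-fence outlier flagging across
the cohort, (3) a genomic-wave metric correlating windowed median logR with a
composition covariate, and (4) a PCA batch check that quantifies clustering
of samples by a labeling factor (time point, subject, slide) via the mean
silhouette coefficient on the first two principal components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .sim import MarkerMap

__all__ = [
    "QcReport",
    "SEX_CHROMOSOMES",
    "exclude_sex_chromosomes",
    "derivative_log_ratio_spread",
    "flag_noise_outliers",
    "wave_metric",
    "pca_batch_check",
]

SEX_CHROMOSOMES = frozenset({"X", "Y", "chrX", "chrY", "x", "y"})


@dataclass
class QcReport:
    sample_id: str
    median_abs_derivative: float
    dlrs: float
    wave_metric: float = float("nan")
    is_outlier: bool = False
    pc_coordinates: tuple[float, ...] = ()
    group_silhouette: dict[str, float] = field(default_factory=dict)


def exclude_sex_chromosomes(
    tracks: pd.DataFrame, marker_map: MarkerMap
) -> tuple[pd.DataFrame, MarkerMap]:
    """Drop X/Y markers from the map and all aligned tracks.

    Idempotent; autosome order is preserved. Emits a warning if nothing is
    left (all-sex-chromosome input).
    """
    chroms = marker_map.df["chromosome"].astype(str)
    keep = ~chroms.isin(SEX_CHROMOSOMES)
    if keep.all():
        return tracks, marker_map
    new_map = MarkerMap(marker_map.df.loc[keep].reset_index(drop=True))
    new_tracks = tracks.loc[keep.to_numpy()].reset_index(drop=True)
    if new_map.n_markers == 0:
        warnings.warn("all markers were on sex chromosomes; empty map remains")
    return new_tracks, new_map


def derivative_log_ratio_spread(
    track: np.ndarray, marker_map: MarkerMap
) -> tuple[float, float]:
    """Median absolute successive logR difference and dLRS.

    Differences are taken only within chromosomes. dLRS is the median
    absolute derivative divided by sqrt(2); for iid noise this is a robust
    spread estimate of the per-probe noise (up to the Gaussian consistency
    factor of the median).

    Returns ``(median_abs_derivative, dlrs)``.
    """
    track = np.asarray(track, dtype=float)
    diffs = []
    for sl in marker_map.chrom_slices().values():
        seg = track[sl]
        if len(seg) >= 2:
            diffs.append(np.abs(np.diff(seg)))
    if not diffs:
        raise ValueError("no within-chromosome differences available for dLRS")
    mad = float(np.median(np.concatenate(diffs)))
    return mad, mad / np.sqrt(2.0)


def flag_noise_outliers(reports: list[QcReport], k: float = 1.5) -> list[QcReport]:
    """Tukey upper-fence flagging on the cohort dLRS values.

    A sample is an outlier if dlrs > Q3 + k*IQR. With fewer than four samples
    the quartiles are unstable: all flags are set False and a warning emitted.
    """
    if len(reports) < 4:
        warnings.warn("fewer than 4 samples: noise outlier flagging skipped")
        for r in reports:
            r.is_outlier = False
        return reports
    values = np.array([r.dlrs for r in reports])
    q1, q3 = np.percentile(values, [25, 75])
    fence = q3 + k * (q3 - q1)
    for r in reports:
        r.is_outlier = bool(r.dlrs > fence)
    return reports


def wave_metric(
    track: np.ndarray,
    marker_map: MarkerMap,
    covariate: np.ndarray,
    window_bp: int = 1_000_000,
) -> float:
    """Absolute Pearson correlation of windowed median logR with a windowed
    composition covariate (true GC if available, the simulator's wave
    covariate otherwise).

    Windows of ``window_bp`` are laid per chromosome; windows with no markers
    are skipped. Returns NaN with fewer than 3 windows; returns 0.0 by
    convention when either windowed series has zero variance.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    track = np.asarray(track, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    med_t, med_c = [], []
    positions = marker_map.positions()
    for sl in marker_map.chrom_slices().values():
        pos = positions[sl]
        t = track[sl]
        c = covariate[sl]
        bins = (pos - pos[0]) // window_bp
        for b in np.unique(bins):
            m = bins == b
            med_t.append(np.median(t[m]))
            med_c.append(np.median(c[m]))
    if len(med_t) < 3:
        return float("nan")
    a = np.asarray(med_t)
    b = np.asarray(med_c)
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(abs(np.corrcoef(a, b)[0, 1]))


def pca_batch_check(
    tracks: pd.DataFrame,
    labelings: dict[str, list] | None = None,
    n_components: int = 2,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Principal components of the sample x marker matrix plus per-labeling
    silhouette on PC1-PC2.

    Markers are mean-centered across samples before the decomposition. The
    number of components is truncated to rank (n_samples - 1). A silhouette
    near 0 means no clustering by that factor; values above ~0.5 indicate
    clear batch structure.

    Returns ``(scores, silhouettes)`` where ``scores`` is a DataFrame indexed
    by sample with columns PC1..PCk.
    """
    X = tracks.to_numpy(dtype=float).T  # samples x markers
    n_samples = X.shape[0]
    if n_samples < 3:
        raise ValueError("PCA batch check needs at least 3 samples")
    X = X - X.mean(axis=0, keepdims=True)
    if not np.any(X):
        raise ValueError("constant logR matrix: zero variance, PCA undefined")
    k = min(n_components, n_samples - 1, X.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    score_df = pd.DataFrame(
        scores, index=list(tracks.columns), columns=[f"PC{i + 1}" for i in range(k)]
    )
    sils: dict[str, float] = {}
    if labelings:
        pc12 = scores[:, : min(2, k)]
        for name, labels in labelings.items():
            labels = np.asarray(labels)
            n_groups = len(set(labels.tolist()))
            if 2 <= n_groups <= n_samples - 1:
                sils[name] = float(silhouette_score(pc12, labels))
            else:
                sils[name] = float("nan")
    return score_df, sils
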