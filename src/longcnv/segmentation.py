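"""Univariate logR segmentation and CNV calling.

Each sample's logR track is segmented chromosome by chromosome in two
phases. First, recursive binary splitting places candidate breakpoints: at
each step the breakpoint minimizing total within-segment sum of squares is
taken (leftmost on ties) and recursion continues until segments cannot be
split without violating the ``min_markers`` floor, so every strong boundary
acquires a breakpoint exactly at its SSE optimum. Second, a merge-pruning
pass joins adjacent segments, worst pair first, while any adjacent pair has
a two-sided Welch t-test p-value above ``max_pairwise_p``; the fixed point
is a partition in which every adjacent pair of segments differs at the
maximum pairwise p criterion. Merging worst-first makes the accepted
breakpoint set monotone in the threshold: lowering ``max_pairwise_p`` only
extends the merge sequence, never adds breakpoints.

A top-down stopping rule (test only the best split of the whole chromosome)
cannot detect a short CNV embedded in a long chromosome — the two halves of
the chromosome have nearly equal means regardless of the CNV — which is why
the pairwise criterion is applied bottom-up over the fine partition instead.
Segment variances entering the Welch test are floored by a robust
derivative-based estimate of the per-probe noise, preventing tiny segments
whose few markers agree by chance from defending spurious boundaries.

Defaults follow common SNP-array practice: max pairwise p 0.005, at least
2 markers per segment, single-point outlier removal, and segment means
filtered at -0.35 / +0.35 logR to call losses and gains.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .sim import MarkerMap

__all__ = [
    "SegmentationParams",
    "Segment",
    "CnvCall",
    "remove_outliers",
    "welch_p_from_stats",
    "welch_p",
    "robust_noise_sd",
    "pairwise_threshold",
    "pairwise_segment_p",
    "segment_values",
    "segment_chromosome",
    "segment_track",
    "call_cnvs",
    "segment_and_call",
    "summarize_lengths",
    "compare_lengths_kruskal",
]

_MAD_FLOOR = 1e-9
_RESPLIT_MAX_MID = 100  # marker cap for the sub-interval re-split scan


@dataclass(frozen=True)
class SegmentationParams:
    max_pairwise_p: float = 0.005
    min_markers: int = 2
    loss_threshold: float = -0.35
    gain_threshold: float = 0.35
    outlier_removal: bool = True
    outlier_mad_k: float = 3.0
    outlier_window: int = 5
    #: divide the pairwise threshold by the number of candidate boundaries,
    #: a familywise bound on spurious breakpoints per chromosome
    selection_adjust: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.max_pairwise_p < 1:
            raise ValueError("max_pairwise_p must be in (0, 1)")
        if self.min_markers < 1:
            raise ValueError("min_markers must be >= 1")
        if not self.loss_threshold < 0 < self.gain_threshold:
            raise ValueError("need loss_threshold < 0 < gain_threshold")


@dataclass(frozen=True)
class Segment:
    """One segment of one chromosome. ``start``/``end`` are global map row
    indices (inclusive); masked markers are spanned by the coordinates but
    excluded from ``n_used``, ``mean_logr`` and ``within_sse``."""

    chromosome: str
    start: int
    end: int
    n_used: int
    mean_logr: float
    within_sse: float

    @property
    def n_markers(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CnvCall:
    sample_id: str
    time_point: int
    chromosome: str
    start_bp: int
    end_bp: int  # half-open
    n_markers: int
    mean_logr: float
    state: str  # "loss" | "gain"
    cnv_id: str = ""

    @property
    def length(self) -> int:
        return self.end_bp - self.start_bp

    def reciprocal_overlap(self, other: "CnvCall") -> float:
        """Smaller of the two mutual overlap fractions (0 if disjoint)."""
        ov = min(self.end_bp, other.end_bp) - max(self.start_bp, other.start_bp)
        if ov <= 0:
            return 0.0
        return min(ov / self.length, ov / other.length)


def _running_median(x: np.ndarray, window: int, exclude_self: bool = False) -> np.ndarray:
    """Windowed median; with ``exclude_self`` the center point is left out
    (Hampel-style), so the reference level is uncontaminated by the value
    being tested."""
    n = len(x)
    if n == 0:
        return x.copy()
    if window >= n and not exclude_self:
        return np.full(n, np.median(x))
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        if exclude_self:
            w = np.concatenate([x[lo:i], x[i + 1 : hi]])
            out[i] = np.median(w) if len(w) else x[i]
        else:
            out[i] = np.median(x[lo:hi])
    return out


def remove_outliers(
    track: np.ndarray, marker_map: MarkerMap, params: SegmentationParams
) -> np.ndarray:
    """Mask isolated single-marker spikes.

    A marker is masked when its residual from the Hampel-style running
    median (window 5, excluding the center, per chromosome) exceeds
    ``outlier_mad_k`` times the chromosome-wide robust spread of those
    residuals (MAD x 1.4826) and neither immediate neighbor sits within that
    tolerance of the marker's value — i.e. the spike is unsupported, so a
    genuine multi-marker shift is never masked. The spread is taken over the
    whole chromosome: a handful of residuals cannot estimate scale, and a
    windowed MAD collapses wherever a few neighbors agree by chance, masking
    genuine signal. Returns a boolean mask, True = outlier.
    """
    track = np.asarray(track, dtype=float)
    mask = np.zeros(len(track), dtype=bool)
    if not params.outlier_removal:
        return mask
    for sl in marker_map.chrom_slices().values():
        x = track[sl]
        n = len(x)
        if n < 3:
            continue
        med = _running_median(x, params.outlier_window, exclude_self=True)
        resid = x - med
        robust_sd = max(1.4826 * float(np.median(np.abs(resid))), _MAD_FLOOR)
        cut = params.outlier_mad_k * robust_sd
        for i in range(1, n - 1):
            if abs(resid[i]) <= cut:
                continue
            if abs(x[i - 1] - x[i]) > cut and abs(x[i + 1] - x[i]) > cut:
                mask[sl.start + i] = True
    return mask


def welch_p_from_stats(
    n1: int,
    m1: float,
    v1: float,
    n2: int,
    m2: float,
    v2: float,
    df1: float | None = None,
    df2: float | None = None,
) -> float:
    """Two-sided Welch t-test p-value from segment summary statistics.

    ``v`` are unbiased variances (0 for single-marker segments); ``df1``/
    ``df2`` override the per-segment degrees of freedom entering the
    Welch-Satterthwaite combination (used when a variance comes from a
    chromosome-wide floor estimated on many differences rather than from the
    segment's own n-1). Degenerate zero-variance pairs short-circuit: equal
    means give p=1, unequal means p=0 (two constant but different segments
    are trivially distinct); "equal" is up to float round-off, since segment
    means of identical levels differ by ulps depending on summation order.
    """

    def _equal(a: float, b: float) -> bool:
        return abs(a - b) <= 1e-9 * max(1.0, abs(a), abs(b))

    se2 = v1 / n1 + v2 / n2
    if se2 <= 0:
        return 1.0 if _equal(m1, m2) else 0.0
    t = (m1 - m2) / np.sqrt(se2)
    d1 = df1 if df1 is not None else n1 - 1
    d2 = df2 if df2 is not None else n2 - 1
    den = 0.0
    if v1 > 0 and d1 > 0:
        den += (v1 / n1) ** 2 / d1
    if v2 > 0 and d2 > 0:
        den += (v2 / n2) ** 2 / d2
    if den == 0:
        return 1.0 if _equal(m1, m2) else 0.0
    df = se2**2 / den
    return float(2.0 * stats.t.sf(abs(t), df))


def welch_p(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    v1 = float(np.var(a, ddof=1)) if len(a) > 1 else 0.0
    v2 = float(np.var(b, ddof=1)) if len(b) > 1 else 0.0
    return welch_p_from_stats(len(a), float(a.mean()), v1, len(b), float(b.mean()), v2)


class _Cum:
    """Prefix sums for O(1) segment statistics over a value vector."""

    def __init__(self, v: np.ndarray):
        self.s = np.concatenate([[0.0], np.cumsum(v)])
        self.q = np.concatenate([[0.0], np.cumsum(v * v)])

    def mean(self, lo: int, hi: int) -> float:
        return (self.s[hi] - self.s[lo]) / (hi - lo)

    def sse(self, lo: int, hi: int) -> float:
        n = hi - lo
        s = self.s[hi] - self.s[lo]
        return max(0.0, (self.q[hi] - self.q[lo]) - s * s / n)

    def var(self, lo: int, hi: int) -> float:
        n = hi - lo
        if n < 2:
            return 0.0
        return self.sse(lo, hi) / (n - 1)

    def welch(
        self, lo: int, k: int, hi: int, var_floor: float = 0.0, floor_df: float = 0.0
    ) -> float:
        """Pairwise Welch-type p between [lo,k) and [k,hi).

        With a positive ``var_floor`` (the chromosome-wide robust noise
        variance), both segments are assigned that common variance with the
        floor estimate's degrees of freedom: per-probe logR noise is
        homoscedastic along a track — a copy-number change shifts the mean,
        not the variance — so the variance information comes from the whole
        chromosome. The empirical variance of a few-marker segment is far
        too unstable for the test either way (a chance-inflated draw can
        make an extreme mean difference look insignificant, a deflated one
        the reverse). With ``var_floor`` 0 this is the classical Welch test
        (plus the zero-variance exact-equality shortcut).
        """
        if var_floor > 0:
            return welch_p_from_stats(
                k - lo, self.mean(lo, k), var_floor,
                hi - k, self.mean(k, hi), var_floor,
                df1=floor_df, df2=floor_df,
            )
        return welch_p_from_stats(
            k - lo, self.mean(lo, k), self.var(lo, k),
            hi - k, self.mean(k, hi), self.var(k, hi),
        )


def robust_noise_sd(v: np.ndarray) -> float:
    """Per-probe noise sd from successive differences.

    median(|diff|) / (0.6745 * sqrt(2)) is consistent for the sd of iid
    Gaussian noise and insensitive to step changes, which affect only a few
    differences.
    """
    v = np.asarray(v, dtype=float)
    if len(v) < 2:
        return 0.0
    return float(np.median(np.abs(np.diff(v)))) / (0.6744897501960817 * np.sqrt(2.0))


def pairwise_threshold(n_markers: int, params: SegmentationParams) -> float:
    """Effective per-pair p threshold for a chromosome of ``n_markers``.

    With ``selection_adjust`` the nominal ``max_pairwise_p`` is divided by
    the number of candidate boundaries (n-1): retained boundaries are the
    extremes among ~n candidates, so an unadjusted per-pair threshold lets
    the tails of that selection through on pure noise.
    """
    if params.selection_adjust and n_markers > 2:
        return params.max_pairwise_p / (n_markers - 1)
    return params.max_pairwise_p


def pairwise_segment_p(
    v: np.ndarray, i: int, j: int, k: int, noise_sd: float | None = None
) -> float:
    """The pairwise p-value the segmenter uses between adjacent segments
    [i,j) and [j,k) of ``v`` (common-noise-variance Welch-type test; see
    ``_Cum.welch``). Exposed so oracles can verify partitions under the
    exact acceptance rule."""
    v = np.asarray(v, dtype=float)
    cum = _Cum(v)
    sd = robust_noise_sd(v) if noise_sd is None else noise_sd
    return cum.welch(i, j, k, sd**2, float(max(len(v) - 1, 1)))


def segment_values(
    v: np.ndarray, params: SegmentationParams, noise_sd: float | None = None
) -> list[tuple[int, int]]:
    """Partition a value vector into half-open ``(lo, hi)`` segments.

    ``noise_sd`` is the per-probe noise level used by the pairwise tests;
    by default it is estimated from ``v`` itself, but callers segmenting one
    chromosome of a longer track should pass the track-wide estimate (more
    differences, less contamination from the segment edges themselves).
    """
    v = np.asarray(v, dtype=float)
    n = len(v)
    if n == 0:
        return []
    cum = _Cum(v)
    var_floor = (robust_noise_sd(v) if noise_sd is None else noise_sd) ** 2
    floor_df = float(max(n - 1, 1))  # the floor is estimated from ~n differences
    threshold = pairwise_threshold(n, params)
    bounds: list[tuple[int, int]] = []

    def split(lo: int, hi: int) -> None:
        length = hi - lo
        if length < 2 * params.min_markers:
            bounds.append((lo, hi))
            return
        ks = np.arange(lo + params.min_markers, hi - params.min_markers + 1)
        nl = ks - lo
        nr = hi - ks
        sl = cum.s[ks] - cum.s[lo]
        sr = cum.s[hi] - cum.s[ks]
        ql = cum.q[ks] - cum.q[lo]
        qr = cum.q[hi] - cum.q[ks]
        sse = (ql - sl * sl / nl) + (qr - sr * sr / nr)
        k = int(ks[np.argmin(sse)])  # leftmost tie by argmin
        split(lo, k)
        split(k, hi)

    split(0, n)
    bounds.sort()

    def merge_pass() -> None:
        # join the adjacent pair with the largest pairwise p while any pair
        # exceeds the threshold
        while len(bounds) > 1:
            ps = [
                cum.welch(bounds[i][0], bounds[i][1], bounds[i + 1][1], var_floor, floor_df)
                for i in range(len(bounds) - 1)
            ]
            worst = int(np.argmax(ps))
            if ps[worst] <= threshold:
                break
            lo, _ = bounds[worst]
            _, hi = bounds.pop(worst + 1)
            bounds[worst] = (lo, hi)

    def refine_pass() -> bool:
        # re-optimize each boundary position by SSE between its two flanking
        # segments; greedy splitting can leave an edge straddled inside an
        # unsplittable fragment, which dilutes the segment mean
        moved = False
        for i in range(len(bounds) - 1):
            lo = bounds[i][0]
            j = bounds[i][1]
            hi = bounds[i + 1][1]
            ks = np.arange(lo + params.min_markers, hi - params.min_markers + 1)
            if len(ks) == 0:
                continue
            sse = np.array([cum.sse(lo, k) + cum.sse(k, hi) for k in ks])
            best = int(ks[np.argmin(sse)])
            if best != j:
                bounds[i] = (lo, best)
                bounds[i + 1] = (best, hi)
                moved = True
        return moved

    def best_subinterval(lo: int, hi: int) -> tuple[float, int, int]:
        # CBS-style two-breakpoint scan: the most aberrant sub-interval
        # [i, i+L) of the segment versus the rest of the segment, ranked by
        # the standardized mean contrast. Mid lengths are capped (short CNVs
        # are the target; the cap keeps the scan linear per length).
        n_seg = hi - lo
        total = cum.s[hi] - cum.s[lo]
        best = (0.0, lo, hi)
        max_mid = min(_RESPLIT_MAX_MID, n_seg - params.min_markers)
        for L in range(params.min_markers, max_mid + 1):
            starts = np.arange(lo, hi - L + 1)
            # each nonempty flank must satisfy the min-markers floor
            left = starts - lo
            right = hi - (starts + L)
            ok = ((left == 0) | (left >= params.min_markers)) & (
                (right == 0) | (right >= params.min_markers)
            )
            if not ok.any():
                continue
            starts = starts[ok]
            sums = cum.s[starts + L] - cum.s[starts]
            m_mid = sums / L
            m_out = (total - sums) / (n_seg - L)
            z = np.abs(m_mid - m_out) / np.sqrt(1.0 / L + 1.0 / (n_seg - L))
            j = int(np.argmax(z))
            if z[j] > best[0]:
                best = (float(z[j]), int(starts[j]), int(starts[j]) + L)
        return best

    def resplit_pass() -> bool:
        # worst-first merging is path dependent: diluted fragments can drag
        # a strong internal boundary below notice and swallow two close
        # segments plus the gap between them — a bump no single split can
        # expose. Re-test each final segment with the sub-interval scan and
        # cut out significant structure.
        changed = False
        i = 0
        while i < len(bounds):
            lo, hi = bounds[i]
            if hi - lo >= 2 * params.min_markers:
                _, a, b = best_subinterval(lo, hi)
                if (a, b) != (lo, hi):
                    n_mid = b - a
                    n_out = (hi - lo) - n_mid
                    m_mid = cum.mean(a, b)
                    m_out = ((cum.s[hi] - cum.s[lo]) - (cum.s[b] - cum.s[a])) / n_out
                    p = welch_p_from_stats(
                        n_mid, m_mid, var_floor, n_out, m_out, var_floor,
                        df1=floor_df, df2=floor_df,
                    )
                    if p <= threshold:
                        pieces = [(lo, a), (a, b), (b, hi)]
                        bounds[i : i + 1] = [pc for pc in pieces if pc[1] > pc[0]]
                        changed = True
                        i += 1  # keep scanning from the mid piece
                        continue
            i += 1
        return changed

    merge_pass()
    for _ in range(5):  # refinement/re-splitting can re-expose mergeable pairs
        changed = refine_pass()
        if changed:
            merge_pass()
        if resplit_pass():
            changed = True
            merge_pass()
        if not changed:
            break
    return bounds


def segment_chromosome(
    track: np.ndarray,
    chrom: str,
    row_slice: slice,
    outlier_mask: np.ndarray,
    params: SegmentationParams,
    noise_sd: float | None = None,
) -> list[Segment]:
    """Segment one chromosome of one track, honouring the outlier mask.

    Masked markers are dropped from the statistics; in the output their
    coordinates attach to the segment on their left (leading masked markers
    to the first segment).
    """
    x = np.asarray(track[row_slice], dtype=float)
    m = np.asarray(outlier_mask[row_slice], dtype=bool)
    used = np.flatnonzero(~m)
    if len(used) == 0:
        # nothing usable: one segment spanning the chromosome with NaN mean
        return [
            Segment(chrom, row_slice.start, row_slice.stop - 1, 0, float("nan"), 0.0)
        ]
    v = x[used]
    bounds = segment_values(v, params, noise_sd=noise_sd)
    cum = _Cum(v)
    out: list[Segment] = []
    n_local = row_slice.stop - row_slice.start
    for i, (lo, hi) in enumerate(bounds):
        start_local = 0 if i == 0 else used[lo]
        end_local = (n_local - 1) if i == len(bounds) - 1 else used[hi] - 1
        out.append(
            Segment(
                chromosome=chrom,
                start=row_slice.start + int(start_local),
                end=row_slice.start + int(end_local),
                n_used=hi - lo,
                mean_logr=cum.mean(lo, hi),
                within_sse=cum.sse(lo, hi),
            )
        )
    return out


def segment_track(
    track: np.ndarray, marker_map: MarkerMap, params: SegmentationParams
) -> list[Segment]:
    """Segment a whole track (all chromosomes).

    The per-probe noise level is estimated once from the whole track
    (within-chromosome successive differences of unmasked markers) and
    shared by every chromosome's pairwise tests.
    """
    mask = remove_outliers(track, marker_map, params)
    diffs = []
    for sl in marker_map.chrom_slices().values():
        keep = np.flatnonzero(~mask[sl])
        if len(keep) >= 2:
            diffs.append(np.diff(np.asarray(track, dtype=float)[sl][keep]))
    noise_sd = None
    if diffs:
        all_diffs = np.concatenate(diffs)
        if len(all_diffs):
            noise_sd = float(np.median(np.abs(all_diffs))) / (
                0.6744897501960817 * np.sqrt(2.0)
            )
    segments: list[Segment] = []
    for chrom, sl in marker_map.chrom_slices().items():
        segments.extend(
            segment_chromosome(track, chrom, sl, mask, params, noise_sd=noise_sd)
        )
    return segments


def call_cnvs(
    segments: list[Segment],
    params: SegmentationParams,
    marker_map: MarkerMap,
    sample_id: str,
    time_point: int,
    id_prefix: str = "CNV",
) -> list[CnvCall]:
    """Filter segments into CNV calls.

    A segment becomes a loss when its mean logR is below ``loss_threshold``
    and a gain when above ``gain_threshold``, provided it retains at least
    ``min_markers`` unmasked markers. Coordinates are half-open base-pair
    intervals: [first marker position, last marker position + 1). Ids are
    assigned in genome order.
    """
    positions = marker_map.positions()
    calls: list[CnvCall] = []
    for seg in segments:
        if seg.n_used < params.min_markers or not np.isfinite(seg.mean_logr):
            continue
        if seg.mean_logr < params.loss_threshold:
            state = "loss"
        elif seg.mean_logr > params.gain_threshold:
            state = "gain"
        else:
            continue
        calls.append(
            CnvCall(
                sample_id=sample_id,
                time_point=time_point,
                chromosome=seg.chromosome,
                start_bp=int(positions[seg.start]),
                end_bp=int(positions[seg.end]) + 1,
                n_markers=seg.n_markers,
                mean_logr=float(seg.mean_logr),
                state=state,
            )
        )
    order = {c: i for i, c in enumerate(marker_map.chromosomes)}
    calls.sort(key=lambda c: (order.get(c.chromosome, 1 << 30), c.start_bp))
    return [replace(c, cnv_id=f"{id_prefix}-{i + 1}") for i, c in enumerate(calls)]


def segment_and_call(
    tracks: pd.DataFrame,
    marker_map: MarkerMap,
    params: SegmentationParams | None = None,
) -> dict[str, list[CnvCall]]:
    """Segment every sample column and return calls keyed by sample name.

    Sample columns are expected to follow the ``<subject>_t<k>`` convention
    of the simulator / Final Report reader.
    """
    from .sim import sample_name  # noqa: F401  (naming convention reference)

    params = params or SegmentationParams()
    out: dict[str, list[CnvCall]] = {}
    for col in tracks.columns:
        subject, _, tp = col.rpartition("_t")
        time_point = int(tp) if subject else 1
        segs = segment_track(tracks[col].to_numpy(), marker_map, params)
        out[col] = call_cnvs(
            segs, params, marker_map, sample_id=subject or col, time_point=time_point
        )
    return out


def summarize_lengths(calls: list[CnvCall]) -> dict[str, float]:
    """Arithmetic mean and median CNV length (bp)."""
    if not calls:
        raise ValueError("no calls to summarize")
    lengths = np.array([c.length for c in calls], dtype=float)
    return {
        "n": len(lengths),
        "mean_bp": float(lengths.mean()),
        "median_bp": float(np.median(lengths)),
    }


def compare_lengths_kruskal(*length_groups) -> float:
    """Kruskal-Wallis p-value comparing CNV length distributions."""
    return float(stats.kruskal(*length_groups).pvalue)
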