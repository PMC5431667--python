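"""Segmentation: outlier masking, partition correctness, CNV call filtering,
and oracle checks against exhaustive small-instance enumeration."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from longcnv.segmentation import (
    CnvCall,
    Segment,
    SegmentationParams,
    _Cum,
    call_cnvs,
    compare_lengths_kruskal,
    pairwise_segment_p,
    pairwise_threshold,
    remove_outliers,
    robust_noise_sd,
    segment_track,
    segment_values,
    summarize_lengths,
    welch_p,
)

from conftest import make_map


# ----------------------------------------------------------- outlier removal

class TestRemoveOutliers:
    def test_isolated_spike_masked(self, default_params):
        m = make_map(50)
        x = np.zeros(50)
        x[25] = 1.0
        mask = remove_outliers(x, m, default_params)
        assert list(np.flatnonzero(mask)) == [25]

    def test_genuine_shift_untouched(self, default_params):
        m = make_map(50)
        x = np.zeros(50)
        x[20:25] = -0.6
        mask = remove_outliers(x, m, default_params)
        assert not mask.any()

    def test_all_equal_no_masks(self, default_params):
        m = make_map(30)
        mask = remove_outliers(np.full(30, 0.2), m, default_params)
        assert not mask.any()

    def test_spikes_found_in_noise(self, default_params):
        m = make_map(2000)
        rng = np.random.default_rng(7)
        x = rng.normal(0, 0.15, 2000)
        x[500] = 1.2
        x[1200] = -1.1
        mask = remove_outliers(x, m, default_params)
        assert mask[500] and mask[1200]
        assert mask.sum() < 0.02 * len(x)  # low false-masking rate


# ----------------------------------------------------------- partitioning

class TestSegmentValues:
    def test_noise_free_forcing(self, default_params):
        x = np.concatenate([np.zeros(20), np.full(10, -0.6), np.zeros(20)])
        assert segment_values(x, default_params) == [(0, 20), (20, 30), (30, 50)]

    def test_pure_noise_rarely_splits(self, default_params):
        ones = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            segs = segment_values(rng.normal(0, 0.15, 200), default_params)
            ones += len(segs) == 1
        assert ones >= 9

    def test_partition_covers_range(self, default_params):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, 0.15, 150)
            x[40:60] -= 0.6
            segs = segment_values(x, default_params)
            assert segs[0][0] == 0 and segs[-1][1] == 150
            for (a, b), (c, d) in zip(segs, segs[1:]):
                assert b == c and b > a

    def test_weighted_means_reproduce_track_mean(self, default_params):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 0.15, 200)
        x[100:110] += 0.8
        segs = segment_values(x, default_params)
        total = sum((b - a) * x[a:b].mean() for a, b in segs)
        assert total == pytest.approx(x.sum(), rel=1e-9)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 0.15, 150)
        x[30:40] -= 0.6
        x[90:95] += 0.5
        n_loose = len(segment_values(x, SegmentationParams(max_pairwise_p=0.05)))
        n_default = len(segment_values(x, SegmentationParams(max_pairwise_p=0.005)))
        n_tight = len(segment_values(x, SegmentationParams(max_pairwise_p=1e-6)))
        assert n_loose >= n_default >= n_tight

    def test_planted_breakpoints_within_one_marker(self, default_params):
        hits = 0
        total = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, 0.15, 120)
            x[50:58] -= 0.6
            segs = segment_values(x, default_params)
            total += 1
            hits += any(abs(lo - 50) <= 1 and abs(hi - 58) <= 1 for lo, hi in segs)
        assert hits >= 0.95 * total


# ------------------------------------------------- exhaustive oracle checks

def _all_partitions(n, min_markers):
    pts = range(min_markers, n - min_markers + 1)
    for r in range(0, n // min_markers):
        for cut in combinations(pts, r):
            prev, ok = 0, True
            for c in cut + (n,):
                if c - prev < min_markers:
                    ok = False
                    break
                prev = c
            if ok:
                yield [0, *cut, n]


def _partition_sse(v, segs):
    cum = _Cum(v)
    return sum(cum.sse(a, b) for a, b in segs)


def _is_accepted(v, segs, params, sd):
    thr = pairwise_threshold(len(v), params)
    return all(
        pairwise_segment_p(v, segs[i][0], segs[i][1], segs[i + 1][1], noise_sd=sd) <= thr
        for i in range(len(segs) - 1)
    )


class TestSmallInstanceOracle:
    def test_accepted_partition_near_dp_optimum(self, default_params):
        """On 20 fixed small instances the returned partition satisfies the
        pairwise acceptance rule and its SSE is within 5% of the exhaustive
        optimum over all accepted partitions."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(8, 13))
            v = rng.normal(0, 0.05, n)
            L = int(rng.integers(3, min(5, n - 5) + 1))
            start = int(rng.integers(2, n - L - 1))
            v[start : start + L] += rng.choice([-0.8, 0.8])

            ours = segment_values(v, default_params)
            sd = robust_noise_sd(v)
            assert _is_accepted(v, ours, default_params, sd)

            best = None
            for part in _all_partitions(n, default_params.min_markers):
                segs = list(zip(part[:-1], part[1:]))
                if not _is_accepted(v, segs, default_params, sd):
                    continue
                sse = _partition_sse(v, segs)
                if best is None or sse < best:
                    best = sse
            assert _partition_sse(v, ours) <= 1.05 * best + 1e-12


class TestWelch:
    def test_matches_scipy_on_generic_samples(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.5, 2, 7)
        assert welch_p(a, b) == pytest.approx(
            stats.ttest_ind(a, b, equal_var=False).pvalue
        )

    def test_zero_variance_shortcuts(self):
        assert welch_p(np.zeros(3), np.zeros(4)) == 1.0
        assert welch_p(np.zeros(3), np.ones(4)) == 0.0


# ----------------------------------------------------------- CNV calling

def _seg(mean, start, end, chrom="1"):
    return Segment(chromosome=chrom, start=start, end=end,
                   n_used=end - start + 1, mean_logr=mean, within_sse=0.0)


class TestCallCnvs:
    def test_threshold_boundaries(self, default_params):
        m = make_map(30)
        segs = [_seg(-0.36, 0, 9), _seg(-0.34, 10, 19), _seg(0.0, 20, 29)]
        calls = call_cnvs(segs, default_params, m, "S1", 1)
        assert len(calls) == 1
        assert calls[0].state == "loss"
        assert calls[0].cnv_id == "CNV-1"

    def test_two_marker_gain_called(self, default_params):
        m = make_map(10)
        segs = [_seg(0.0, 0, 3), _seg(0.40, 4, 5), _seg(0.0, 6, 9)]
        calls = call_cnvs(segs, default_params, m, "S1", 2)
        assert [c.state for c in calls] == ["gain"]
        assert calls[0].n_markers == 2

    def test_whole_chromosome_zero_no_calls(self, default_params):
        m = make_map(20)
        assert call_cnvs([_seg(0.0, 0, 19)], default_params, m, "S1", 1) == []

    def test_half_open_bp_coordinates(self, default_params):
        m = make_map(10, spacing=1000)
        segs = [_seg(-0.5, 2, 4), _seg(0.0, 5, 9), _seg(0.0, 0, 1)]
        calls = call_cnvs(segs, default_params, m, "S1", 1)
        call = calls[0]
        assert call.start_bp == 3000  # position of marker 2
        assert call.end_bp == 5001  # position of marker 4, +1 for half-open
        assert call.length == call.end_bp - call.start_bp


class TestLengthSummaries:
    def test_direct_arithmetic(self):
        calls = [
            CnvCall("S1", 1, "1", 0, 10_000, 3, -0.5, "loss"),
            CnvCall("S1", 1, "1", 50_000, 70_000, 3, -0.5, "loss"),
            CnvCall("S1", 1, "2", 0, 90_000, 3, -0.5, "loss"),
        ]
        out = summarize_lengths(calls)
        assert out["mean_bp"] == pytest.approx(40_000)
        assert out["median_bp"] == pytest.approx(20_000)

    def test_single_call(self):
        calls = [CnvCall("S1", 1, "1", 0, 31_000, 3, -0.5, "loss")]
        out = summarize_lengths(calls)
        assert out["mean_bp"] == out["median_bp"] == 31_000

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            summarize_lengths([])

    def test_kruskal_matches_rank_statistic(self):
        # 6-element toy input: compute H from the ranks directly and compare
        # the chi-square upper tail with the library result
        a, b = [10.0, 20.0, 90.0], [15.0, 25.0, 80.0]
        pooled = sorted(a + b)
        ranks = {v: i + 1 for i, v in enumerate(pooled)}
        n, k = 6, 2
        h = 12 / (n * (n + 1)) * sum(
            len(g) * (np.mean([ranks[v] for v in g]) - (n + 1) / 2) ** 2
            for g in (a, b)
        )
        assert compare_lengths_kruskal(a, b) == pytest.approx(
            float(stats.chi2.sf(h, k - 1))
        )


class TestSegmentTrack:
    def test_masked_marker_spanned_not_counted(self, default_params):
        m = make_map(40)
        x = np.zeros(40)
        x[10:20] = -0.6
        x[15] = 1.0  # spike inside the CNV
        segs = segment_track(x, m, default_params)
        cnv = [s for s in segs if s.mean_logr < -0.3]
        assert len(cnv) == 1
        assert (cnv[0].start, cnv[0].end) == (10, 19)
        assert cnv[0].n_used == 9  # spike excluded from the statistics
        assert cnv[0].mean_logr == pytest.approx(-0.6)
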