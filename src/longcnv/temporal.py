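"""Longitudinal matching and classification of CNV calls.

Calls from the three sampling time points of one subject are grouped into
trajectories by single-linkage clustering under a reciprocal-overlap
predicate (default 0.5: each member must cover, and be covered by, the other
to at least half its length). A trajectory's presence pattern over
(t1, t2, t3) determines its temporal class:

====================  ==============
pattern               class
====================  ==============
(1,1,1)               constant
(0,1,1)               de_novo_23
(0,0,1)               de_novo_3
any other non-empty   inconsistent
====================  ==============

Constant CNVs were present from the first sampling; de novo CNVs arose
during the study (a call first seen at t2 must persist to t3 to count);
everything else — patterns ending in absence, or the never-observed
(1,0,1) resurrection pattern — is inconsistent with the accumulation model
and excluded from headline statistics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .segmentation import CnvCall

__all__ = [
    "CnvTrajectory",
    "DE_NOVO_CLASSES",
    "classify",
    "match_calls",
    "genome_coverage",
    "class_coverage_statistic",
    "denovo_proportion_test",
    "division_corrected_rate",
    "estimate_divisions_in_vitro",
    "cohort_summary",
    "round_half_away",
    "round_sig",
]

DE_NOVO_CLASSES = ("de_novo_23", "de_novo_3")


@dataclass
class CnvTrajectory:
    subject_id: str
    chromosome: str
    merged_start_bp: int
    merged_end_bp: int
    state: str
    presence_pattern: tuple[bool, ...]
    temporal_class: str
    member_call_ids: tuple[str, ...] = ()
    #: set for the (1,0,1) pattern the accumulation model predicts never occurs
    resurrection_flag: bool = False
    notes: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.merged_end_bp - self.merged_start_bp


def classify(pattern: tuple[bool, ...]) -> str:
    """Temporal class of a three-time-point presence pattern."""
    if len(pattern) != 3:
        raise ValueError("presence pattern must cover exactly three time points")
    if not any(pattern):
        raise ValueError("presence pattern must have at least one true entry")
    p = tuple(bool(x) for x in pattern)
    if p == (True, True, True):
        return "constant"
    if p == (False, True, True):
        return "de_novo_23"
    if p == (False, False, True):
        return "de_novo_3"
    return "inconsistent"


def match_calls(
    calls: list[CnvCall], min_reciprocal_overlap: float = 0.5
) -> list[CnvTrajectory]:
    """Group one subject's calls into trajectories.

    Calls must share the subject; same-chromosome, same-state calls are
    linked whenever their reciprocal overlap reaches the threshold, and
    connected components become trajectories (single linkage). Two calls
    from the same time point falling into one component are collapsed into
    per-time-point presence with a warning.
    """
    if not 0 < min_reciprocal_overlap <= 1:
        raise ValueError("min_reciprocal_overlap must be in (0, 1]")
    if not calls:
        return []
    subjects = {c.sample_id for c in calls}
    if len(subjects) > 1:
        raise ValueError(f"match_calls expects one subject, got {sorted(subjects)}")
    subject = subjects.pop()
    n_timepoints = 3

    # union-find over calls within (chromosome, state) groups
    parent = list(range(len(calls)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    groups: dict[tuple[str, str], list[int]] = {}
    for i, c in enumerate(calls):
        groups.setdefault((c.chromosome, c.state), []).append(i)
    for idxs in groups.values():
        idxs.sort(key=lambda i: calls[i].start_bp)
        for a in range(len(idxs)):
            for b in range(a + 1, len(idxs)):
                ca, cb = calls[idxs[a]], calls[idxs[b]]
                if cb.start_bp >= ca.end_bp:
                    break  # sorted by start: nothing further can touch ca
                if ca.reciprocal_overlap(cb) >= min_reciprocal_overlap:
                    union(idxs[a], idxs[b])

    components: dict[int, list[int]] = {}
    for i in range(len(calls)):
        components.setdefault(find(i), []).append(i)

    trajectories: list[CnvTrajectory] = []
    for members in components.values():
        mc = [calls[i] for i in members]
        pattern = [False] * n_timepoints
        seen_tp: set[int] = set()
        dup = False
        for c in mc:
            if not 1 <= c.time_point <= n_timepoints:
                raise ValueError(f"time point out of range: {c.time_point}")
            if c.time_point in seen_tp:
                dup = True
            seen_tp.add(c.time_point)
            pattern[c.time_point - 1] = True
        if dup:
            warnings.warn(
                f"multiple calls at one time point merged into a single "
                f"trajectory for subject {subject}"
            )
        pat = tuple(pattern)
        cls = classify(pat)
        trajectories.append(
            CnvTrajectory(
                subject_id=subject,
                chromosome=mc[0].chromosome,
                merged_start_bp=min(c.start_bp for c in mc),
                merged_end_bp=max(c.end_bp for c in mc),
                state=mc[0].state,
                presence_pattern=pat,
                temporal_class=cls,
                member_call_ids=tuple(c.cnv_id for c in mc),
                resurrection_flag=(pat == (True, False, True)),
            )
        )
    trajectories.sort(key=lambda t: (t.chromosome, t.merged_start_bp))
    return trajectories


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    last_end = None
    for s, e in sorted(intervals):
        if last_end is None or s >= last_end:
            total += e - s
            last_end = e
        elif e > last_end:
            total += e - last_end
            last_end = e
    return total


def genome_coverage(trajectories: list[CnvTrajectory]) -> pd.DataFrame:
    """Cumulative CNV genome coverage (bp) per subject per time point.

    At time point t the coverage is the union, per chromosome, of the merged
    intervals of all constant/de novo trajectories present at any time <= t.
    Inconsistent trajectories are excluded. The cumulative construction makes
    coverage non-decreasing in t within each subject.
    """
    rows = []
    subjects = sorted({t.subject_id for t in trajectories})
    for subject in subjects:
        mine = [
            t
            for t in trajectories
            if t.subject_id == subject and t.temporal_class != "inconsistent"
        ]
        for tp in range(1, 4):
            per_chrom: dict[str, list[tuple[int, int]]] = {}
            for t in mine:
                if any(t.presence_pattern[:tp]):
                    per_chrom.setdefault(t.chromosome, []).append(
                        (t.merged_start_bp, t.merged_end_bp)
                    )
            cov = sum(_union_length(v) for v in per_chrom.values())
            rows.append({"subject_id": subject, "time_point": tp, "coverage_bp": cov})
    return pd.DataFrame(rows, columns=["subject_id", "time_point", "coverage_bp"])


def class_coverage_statistic(trajectories: list[CnvTrajectory], cls: str) -> float:
    """Median merged length x trajectory count (bp) for one temporal class
    (with the de novo classes pooled under ``"de_novo"``)."""
    if cls == "de_novo":
        mine = [t for t in trajectories if t.temporal_class in DE_NOVO_CLASSES]
    else:
        mine = [t for t in trajectories if t.temporal_class == cls]
    if not mine:
        raise ValueError(f"no trajectories in class {cls!r}")
    lengths = np.array([t.length for t in mine], dtype=float)
    return float(np.median(lengths)) * len(mine)


def denovo_proportion_test(
    k1_denovo: int, n1_total: int, k2_denovo: int, n2_total: int
) -> float:
    """Exact two-sided binomial test of group 2's de novo proportion against
    the group-1 proportion as the null.

    Two-sided by summation of outcome probabilities not exceeding the
    observed outcome's probability (the common exact-test convention).
    """
    for k, n in ((k1_denovo, n1_total), (k2_denovo, n2_total)):
        if not 0 <= k <= n:
            raise ValueError("need 0 <= k <= n in both groups")
    if n1_total == 0 or n2_total == 0:
        raise ValueError("group totals must be positive")
    p0 = k1_denovo / n1_total
    return float(stats.binomtest(k2_denovo, n2_total, p0, alternative="two-sided").pvalue)


def division_corrected_rate(n_denovo: int, n_divisions: float) -> float:
    """De novo CNVs per estimated cell division."""
    if n_divisions <= 0:
        raise ValueError("n_divisions must be positive")
    return n_denovo / n_divisions


def estimate_divisions_in_vitro(
    n_passages: float, doublings_per_passage: float = 2.5
) -> float:
    """Cell divisions over a passaging window: passages x doublings/passage."""
    if n_passages < 0 or doublings_per_passage < 0:
        raise ValueError("inputs must be non-negative")
    return n_passages * doublings_per_passage


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention used for reported ratios)."""
    factor = 10**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures, half away from zero."""
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    return round_half_away(x, sig - 1 - exponent)


def cohort_summary(trajectories: list[CnvTrajectory]) -> dict:
    """Headline cohort statistics over a set of trajectories.

    Inconsistent trajectories are retained in the per-class tallies but
    excluded from the de novo fraction, coverage and per-subject figures.
    """
    classes = ("constant", "de_novo_23", "de_novo_3", "inconsistent")
    by_class = {c: [t for t in trajectories if t.temporal_class == c] for c in classes}
    consistent = [t for t in trajectories if t.temporal_class != "inconsistent"]
    n_denovo = len(by_class["de_novo_23"]) + len(by_class["de_novo_3"])
    n_constant = len(by_class["constant"])
    subjects = sorted({t.subject_id for t in trajectories})

    per_subject = {}
    for s in subjects:
        mine = [t for t in consistent if t.subject_id == s]
        per_subject[s] = {
            "constant": sum(t.temporal_class == "constant" for t in mine),
            "de_novo": sum(t.temporal_class in DE_NOVO_CLASSES for t in mine),
        }
    const_counts = [v["constant"] for v in per_subject.values()]
    dn_counts = [v["de_novo"] for v in per_subject.values()]

    per_chrom: dict[str, int] = {}
    for t in consistent:
        per_chrom[t.chromosome] = per_chrom.get(t.chromosome, 0) + 1

    summary = {
        "n_trajectories": len(trajectories),
        "class_counts": {c: len(v) for c, v in by_class.items()},
        "n_constant": n_constant,
        "n_de_novo": n_denovo,
        "de_novo_fraction": (
            n_denovo / (n_denovo + n_constant) if (n_denovo + n_constant) else float("nan")
        ),
        "loss_count": sum(t.state == "loss" for t in consistent),
        "gain_count": sum(t.state == "gain" for t in consistent),
        "per_subject": per_subject,
        "mean_constant_per_subject": float(np.mean(const_counts)) if const_counts else 0.0,
        "mean_de_novo_per_subject": float(np.mean(dn_counts)) if dn_counts else 0.0,
        "median_constant_per_subject": float(np.median(const_counts)) if const_counts else 0.0,
        "median_de_novo_per_subject": float(np.median(dn_counts)) if dn_counts else 0.0,
        "per_chromosome_counts": dict(sorted(per_chrom.items())),
        "resurrection_count": sum(t.resurrection_flag for t in trajectories),
    }
    for cls in ("constant", "de_novo"):
        try:
            summary[f"{cls}_coverage_statistic_bp"] = class_coverage_statistic(
                trajectories, cls
            )
        except ValueError:
            summary[f"{cls}_coverage_statistic_bp"] = 0.0
    lengths_const = [t.length for t in by_class["constant"]]
    lengths_dn = [t.length for t in consistent if t.temporal_class in DE_NOVO_CLASSES]
    summary["median_length_constant_bp"] = (
        float(np.median(lengths_const)) if lengths_const else float("nan")
    )
    summary["median_length_de_novo_bp"] = (
        float(np.median(lengths_dn)) if lengths_dn else float("nan")
    )
    return summary
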