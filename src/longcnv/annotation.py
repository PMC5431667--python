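"""Interval annotation and enrichment statistics for CNV sets.

Covers: any-overlap annotation of CNV intervals against gene / QTL interval
features (sweep-line over start-sorted inputs), the four-way Venn partition
of gene lists, per-trait-class binomial enrichment of de novo versus
constant CNVs, and hypergeometric gene-set enrichment with
Benjamini-Hochberg adjustment reported as C / O / E / R / rawP / adjP.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Feature",
    "EnrichmentResult",
    "QTL_CLASSES",
    "overlap",
    "venn_partition",
    "qtl_class_enrichment",
    "geneset_enrichment",
]

QTL_CLASSES = (
    "Health",
    "Meat_and_carcass",
    "Milk",
    "Production",
    "Reproduction",
    "Exterior",
)


@dataclass(frozen=True)
class Feature:
    """A genomic interval feature, half-open [start_bp, end_bp)."""

    chromosome: str
    start_bp: int
    end_bp: int
    name: str
    kind: str = "gene"  # "gene" | "qtl"
    trait_class: str | None = None

    def __post_init__(self) -> None:
        if self.end_bp <= self.start_bp:
            raise ValueError(f"feature {self.name}: end must exceed start")
        if self.kind == "qtl" and self.trait_class is None:
            raise ValueError(f"QTL feature {self.name} needs a trait_class")
        if self.kind == "gene" and self.trait_class is not None:
            raise ValueError(f"gene feature {self.name} must not carry a trait_class")


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    C: int  # reference genes in category
    O: int  # observed overlap
    E: float  # expected count
    R: float  # enrichment ratio O/E
    raw_p: float
    adj_p: float


def overlap(
    intervals: Sequence[tuple[str, int, int]],
    features: Sequence[Feature],
    min_overlap_bp: int = 1,
) -> list[list[Feature]]:
    """Features sharing at least ``min_overlap_bp`` bases with each interval.

    ``intervals`` are (chromosome, start_bp, end_bp) half-open. A sweep over
    start-sorted features per chromosome; for each query the active set is
    pruned by feature end. Output order follows the input interval order;
    each feature list is ordered by feature start.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    by_chrom: dict[str, list[Feature]] = {}
    for f in features:
        by_chrom.setdefault(f.chromosome, []).append(f)
    for fs in by_chrom.values():
        fs.sort(key=lambda f: (f.start_bp, f.end_bp, f.name))

    order = np.argsort([iv[1] for iv in intervals], kind="stable")
    results: list[list[Feature]] = [[] for _ in intervals]
    cursor: dict[str, int] = {}
    active: dict[str, list[Feature]] = {}
    for qi in order:
        chrom, qs, qe = intervals[qi]
        fs = by_chrom.get(chrom, [])
        i = cursor.get(chrom, 0)
        act = active.setdefault(chrom, [])
        while i < len(fs) and fs[i].start_bp < qe:
            act.append(fs[i])
            i += 1
        cursor[chrom] = i
        act[:] = [f for f in act if f.end_bp > qs]
        hits = [
            f
            for f in act
            if min(qe, f.end_bp) - max(qs, f.start_bp) >= min_overlap_bp
        ]
        hits.sort(key=lambda f: (f.start_bp, f.end_bp, f.name))
        results[qi] = hits
    return results


def venn_partition(gene_sets: Mapping[str, set]) -> dict[frozenset, int]:
    """Counts of all exclusive regions of a Venn diagram over named sets.

    For four sets this yields the 15 non-empty regions; each element of the
    union is counted in exactly one region (the frozenset of the names of
    the sets containing it).
    """
    names = list(gene_sets)
    if not 2 <= len(names) <= 4:
        raise ValueError("venn_partition supports 2-4 sets")
    regions: dict[frozenset, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            regions[frozenset(combo)] = 0
    for gene in set().union(*gene_sets.values()):
        membership = frozenset(n for n in names if gene in gene_sets[n])
        regions[membership] += 1
    return regions


def _counts_per_class(
    intervals: Sequence[tuple[str, int, int]],
    qtl_features: Sequence[Feature],
    classes: Iterable[str],
) -> dict[str, int]:
    hits = overlap(intervals, qtl_features)
    counts = {c: 0 for c in classes}
    for fs in hits:
        present = {f.trait_class for f in fs if f.kind == "qtl"}
        for c in present:
            if c in counts:
                counts[c] += 1  # a CNV counts once per class
    return counts


def qtl_class_enrichment(
    denovo_intervals: Sequence[tuple[str, int, int]],
    constant_intervals: Sequence[tuple[str, int, int]],
    qtl_features: Sequence[Feature],
    classes: Sequence[str] = QTL_CLASSES,
) -> dict[str, dict]:
    """Binomial enrichment of QTL trait classes in de novo vs constant CNVs.

    For each class, the number of de novo CNVs overlapping at least one QTL
    of the class is tested (exact two-sided binomial, n = total de novo
    CNVs) against the null proportion observed in the constant group. A
    continuity floor of 0.5/n_constant keeps the null proportion off 0 and 1
    when the constant group is all-or-nothing.
    """
    if not denovo_intervals or not constant_intervals:
        raise ValueError("both CNV groups must be non-empty")
    n_dn = len(denovo_intervals)
    n_const = len(constant_intervals)
    dn_counts = _counts_per_class(denovo_intervals, qtl_features, classes)
    const_counts = _counts_per_class(constant_intervals, qtl_features, classes)
    out: dict[str, dict] = {}
    floor = 0.5 / n_const
    for c in classes:
        p0 = const_counts[c] / n_const
        p0 = min(max(p0, floor), 1.0 - floor)
        p = float(stats.binomtest(dn_counts[c], n_dn, p0, alternative="two-sided").pvalue)
        out[c] = {
            "de_novo_count": dn_counts[c],
            "de_novo_total": n_dn,
            "constant_count": const_counts[c],
            "constant_total": n_const,
            "null_proportion": p0,
            "p_value": p,
        }
    return out


def geneset_enrichment(
    analyzed_genes: Iterable[str],
    categories: Mapping[str, set],
    reference_size: int,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of each category in a gene list.

    Per category with C reference genes: O = observed members of the
    analyzed list, E = C*k/N (k analyzed genes, N reference universe size),
    R = O/E, rawP = upper-tail hypergeometric P(X >= O), adjP =
    Benjamini-Hochberg across the tested categories. Categories follow the
    input ordering.
    """
    analyzed = set(analyzed_genes)
    k = len(analyzed)
    N = reference_size
    if k > N:
        raise ValueError("analyzed list larger than the reference universe")
    raws = []
    rows = []
    for name, members in categories.items():
        C = len(members)
        O = len(analyzed & members)
        E = C * k / N
        R = O / E if E > 0 else 0.0
        if O == 0:
            R = 0.0
        raw_p = float(stats.hypergeom.sf(O - 1, N, C, k)) if O > 0 else 1.0
        raws.append(raw_p)
        rows.append((name, C, O, E, R, raw_p))
    if not rows:
        return []
    adj = multipletests(raws, method="fdr_bh")[1]
    return [
        EnrichmentResult(name, C, O, E, R, raw_p, float(a))
        for (name, C, O, E, R, raw_p), a in zip(rows, adj)
    ]
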