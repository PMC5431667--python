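"""qPCR copy-number validation against array calls.

Relative quantities are computed per sample with the efficiency-corrected
ddCq model against a pooled first-time-point control and two normalizer
genes (geometric mean of the normalizer ratios). Copy-number status at the
2nd and 3rd time points is derived from the RQ ratio to the 1st time point,
and agreement with array-based status predictions is scored as a
percentage of matching (assay, sample, time point) pairs.

Per-assay amplification efficiencies (amplification factor per cycle, 2.0
for perfect doubling) are inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "QpcrRecord",
    "relative_quantity",
    "timepoint_ratio_and_call",
    "agreement",
]


@dataclass(frozen=True)
class QpcrRecord:
    assay_id: str
    sample_id: str
    time_point: int
    cq: tuple[float, ...]  # replicate Cq values
    efficiency: float = 2.0

    def __post_init__(self) -> None:
        if not self.cq:
            raise ValueError("at least one replicate Cq required")
        if any(c <= 0 for c in self.cq):
            raise ValueError("Cq values must be positive")
        if not 1.0 < self.efficiency <= 2.0:
            raise ValueError("efficiency must be in (1, 2]")

    @property
    def mean_cq(self) -> float:
        return float(np.mean(self.cq))


def _mean_cq(records: Sequence[QpcrRecord], assay: str, sample: str) -> float:
    cqs = [r.mean_cq for r in records if r.assay_id == assay and r.sample_id == sample]
    if not cqs:
        raise KeyError(f"no Cq records for assay {assay!r}, sample {sample!r}")
    return float(np.mean(cqs))


def relative_quantity(
    records: Sequence[QpcrRecord],
    target_assay: str,
    normalizer_assays: Sequence[str],
    control_sample: str,
    samples: Sequence[str] | None = None,
) -> dict[str, float]:
    """Normalized relative quantity of the target locus per sample.

    RQ(s) = E_t^(Cq_control - Cq_s) for the target, divided by the geometric
    mean over the normalizers r of E_r^(Cq_control - Cq_s). Replicates are
    averaged on the Cq scale before exponentiation. The control sample (a
    pool of all first-time-point DNAs, representing diploid copy number at
    every tested locus) has RQ 1 by construction.
    """
    if len(normalizer_assays) < 1:
        raise ValueError("at least one normalizer assay required")
    eff = {r.assay_id: r.efficiency for r in records}
    for a in (target_assay, *normalizer_assays):
        if a not in eff:
            raise KeyError(f"missing records for normalizer/target gene {a!r}")
    if samples is None:
        samples = sorted(
            {r.sample_id for r in records if r.assay_id == target_assay}
            - {control_sample}
        )
    out: dict[str, float] = {}
    for s in samples:
        dq_t = _mean_cq(records, target_assay, control_sample) - _mean_cq(
            records, target_assay, s
        )
        target_q = eff[target_assay] ** dq_t
        ref_qs = []
        for a in normalizer_assays:
            dq_r = _mean_cq(records, a, control_sample) - _mean_cq(records, a, s)
            ref_qs.append(eff[a] ** dq_r)
        out[s] = float(target_q / np.exp(np.mean(np.log(ref_qs))))
    return out


def timepoint_ratio_and_call(
    rq_by_timepoint: Mapping[int, float],
    loss_cut: float = 0.75,
    gain_cut: float = 1.25,
) -> dict[int, dict]:
    """Copy-number status of later time points relative to the first.

    ratio_t = RQ_t / RQ_1; status is ``loss`` when ratio <= loss_cut,
    ``gain`` when ratio >= gain_cut (both boundaries inclusive), otherwise
    ``no-change``.
    """
    if 1 not in rq_by_timepoint:
        raise ValueError("first-time-point RQ required")
    rq1 = rq_by_timepoint[1]
    if rq1 <= 0:
        raise ValueError("first-time-point RQ must be positive")
    out: dict[int, dict] = {}
    for tp in sorted(rq_by_timepoint):
        if tp == 1:
            continue
        ratio = rq_by_timepoint[tp] / rq1
        if ratio <= loss_cut:
            status = "loss"
        elif ratio >= gain_cut:
            status = "gain"
        else:
            status = "no-change"
        out[tp] = {"ratio": ratio, "status": status}
    return out


def agreement(
    calls_qpcr: Mapping[tuple, str], calls_array: Mapping[tuple, str]
) -> float:
    """Percentage of (assay, sample, time point) pairs with matching status.

    Only keys present in both mappings are compared; an empty pairing is an
    error.
    """
    shared = sorted(set(calls_qpcr) & set(calls_array))
    if not shared:
        raise ValueError("no paired qPCR/array calls to compare")
    n_match = sum(calls_qpcr[k] == calls_array[k] for k in shared)
    return 100.0 * n_match / len(shared)
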