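"""End-to-end report: simulate (or ingest) -> QC -> segment -> classify ->
annotate/enrich, assembled into one cohort summary."""

from __future__ import annotations

import logging
from collections import defaultdict

from . import annotation as ann
from . import io as lio
from . import qc as lqc
from . import segmentation as seg
from . import temporal
from .config import PipelineConfig
from .sim import MarkerMap, TruthCnv, simulate_cohort, wave_covariate

__all__ = ["run_report", "evaluate_recovery", "PipelineError"]

log = logging.getLogger("longcnv")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return out

        return wrapper

    return deco


def evaluate_recovery(
    truth: list[TruthCnv],
    trajectories: list[temporal.CnvTrajectory],
    marker_map: MarkerMap,
    min_reciprocal_overlap: float = 0.5,
) -> dict:
    """Score recovered trajectories against planted truth.

    A truth CNV counts as recovered when some trajectory of the same subject
    and state overlaps it reciprocally at the threshold; it is recovered
    *with correct class* when that trajectory's temporal class additionally
    equals the class of the planted presence pattern. Planted inconsistent
    patterns are scored against the inconsistent class.
    """
    positions = marker_map.positions()
    by_subject: dict[str, list[temporal.CnvTrajectory]] = defaultdict(list)
    for t in trajectories:
        by_subject[t.subject_id].append(t)
    n = len(truth)
    recovered = 0
    correct_class = 0
    for tc in truth:
        t_start = int(positions[tc.start_marker_index])
        t_end = int(positions[tc.end_marker_index]) + 1
        t_len = t_end - t_start
        want = temporal.classify(tc.presence_pattern)
        hit = False
        hit_class = False
        for tr in by_subject.get(tc.subject_id, []):
            if tr.chromosome != tc.chromosome or tr.state != tc.state:
                continue
            ov = min(t_end, tr.merged_end_bp) - max(t_start, tr.merged_start_bp)
            if ov <= 0:
                continue
            if ov / t_len >= min_reciprocal_overlap and ov / tr.length >= min_reciprocal_overlap:
                hit = True
                if tr.temporal_class == want:
                    hit_class = True
        recovered += hit
        correct_class += hit_class
    return {
        "n_truth": n,
        "n_recovered": recovered,
        "n_correct_class": correct_class,
        "recovery_fraction": recovered / n if n else float("nan"),
        "correct_class_fraction": correct_class / n if n else float("nan"),
    }


def run_report(config: PipelineConfig | None = None, out_dir=None) -> dict:
    """Run the full pipeline under one config and return the cohort summary.

    Without real-data paths, a synthetic cohort from ``config.sim`` is
    generated, in which case the summary also carries the planted-truth
    recovery score. When ``out_dir`` is given, figures-ready tables (calls,
    trajectories, coverage) and the summary JSON are written there.
    """
    config = config or PipelineConfig()

    @_stage("simulate/ingest")
    def _input():
        if config.paths.final_report:
            tracks, marker_map = lio.read_final_report(config.paths.final_report)
            return marker_map, None, tracks
        if config.paths.logr_tsv:
            tracks, marker_map = lio.read_logr_tsv(config.paths.logr_tsv)
            return marker_map, None, tracks
        return simulate_cohort(config.sim.to_sim_config())

    marker_map, truth, tracks = _input()
    log.info("input: %d markers, %d tracks", marker_map.n_markers, len(tracks.columns))

    @_stage("qc")
    def _qc():
        tr, mm = lqc.exclude_sex_chromosomes(tracks, marker_map)
        cov = wave_covariate(mm, config.sim.to_sim_config())
        reports = []
        for col in tr.columns:
            x = tr[col].to_numpy()
            mad, dlrs = lqc.derivative_log_ratio_spread(x, mm)
            reports.append(
                lqc.QcReport(
                    sample_id=col,
                    median_abs_derivative=mad,
                    dlrs=dlrs,
                    wave_metric=lqc.wave_metric(x, mm, cov),
                )
            )
        lqc.flag_noise_outliers(reports)
        labelings = {}
        cols = list(tr.columns)
        if all("_t" in c for c in cols) and len(cols) >= 3:
            labelings = {
                "time_point": [c.rpartition("_t")[2] for c in cols],
                "subject": [c.rpartition("_t")[0] for c in cols],
            }
        try:
            _, sils = lqc.pca_batch_check(tr, labelings)
        except ValueError:
            sils = {}
        return tr, mm, reports, sils

    tracks, marker_map, qc_reports, silhouettes = _qc()
    log.info("qc: %d samples, %d noise outliers", len(qc_reports), sum(r.is_outlier for r in qc_reports))

    @_stage("segment")
    def _segment():
        return seg.segment_and_call(tracks, marker_map, config.segmentation.to_params())

    calls_by_sample = _segment()
    all_calls = [c for calls in calls_by_sample.values() for c in calls]
    log.info("segment: %d CNV calls", len(all_calls))

    @_stage("classify")
    def _classify():
        by_subject: dict[str, list[seg.CnvCall]] = defaultdict(list)
        for c in all_calls:
            by_subject[c.sample_id].append(c)
        trajectories = []
        for subject in sorted(by_subject):
            trajectories.extend(
                temporal.match_calls(
                    by_subject[subject], config.matching.min_reciprocal_overlap
                )
            )
        return trajectories

    trajectories = _classify()
    summary = temporal.cohort_summary(trajectories)
    coverage = temporal.genome_coverage(trajectories)
    summary["qc"] = {
        "dlrs": {r.sample_id: r.dlrs for r in qc_reports},
        "noise_outliers": [r.sample_id for r in qc_reports if r.is_outlier],
        "pca_silhouettes": silhouettes,
    }
    summary["coverage_by_timepoint"] = coverage.to_dict(orient="records")
    summary["n_calls"] = len(all_calls)

    @_stage("annotate/enrich")
    def _annotate():
        out: dict = {}
        consistent = [t for t in trajectories if t.temporal_class != "inconsistent"]
        dn = [t for t in consistent if t.temporal_class in temporal.DE_NOVO_CLASSES]
        const = [t for t in consistent if t.temporal_class == "constant"]
        as_iv = lambda ts: [(t.chromosome, t.merged_start_bp, t.merged_end_bp) for t in ts]
        if config.paths.genes:
            genes = lio.read_gene_features(config.paths.genes)
            hits_dn = ann.overlap(as_iv(dn), genes, config.enrichment.min_overlap_bp)
            hits_const = ann.overlap(as_iv(const), genes, config.enrichment.min_overlap_bp)
            genes_dn = {f.name for fs in hits_dn for f in fs}
            genes_const = {f.name for fs in hits_const for f in fs}
            out["genes_de_novo"] = sorted(genes_dn)
            out["genes_constant"] = sorted(genes_const)
            out["venn"] = {
                "&".join(sorted(k)): v
                for k, v in ann.venn_partition(
                    {"de_novo": genes_dn, "constant": genes_const}
                ).items()
            }
            if config.paths.gmt and genes_dn:
                gmt = lio.read_gmt(config.paths.gmt)
                out["geneset_enrichment"] = [
                    r.__dict__
                    for r in ann.geneset_enrichment(
                        genes_dn, gmt, config.enrichment.reference_size
                    )
                ]
        if config.paths.qtls and dn and const:
            qtls = lio.read_qtl_table(config.paths.qtls)
            out["qtl_enrichment"] = ann.qtl_class_enrichment(
                as_iv(dn), as_iv(const), qtls
            )
        return out

    summary["annotation"] = _annotate()

    if truth is not None:
        summary["recovery"] = evaluate_recovery(
            truth, trajectories, marker_map, config.matching.min_reciprocal_overlap
        )

    if out_dir is not None:
        from pathlib import Path

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        lio.write_calls_tsv(all_calls, out_dir / "calls.tsv")
        lio.write_trajectories_tsv(trajectories, out_dir / "trajectories.tsv")
        coverage.to_csv(out_dir / "coverage.tsv", sep="\t", index=False)
        lio.write_json_summary(summary, out_dir / "summary.json")
    return summary
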