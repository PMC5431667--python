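"""Readers and writers for the external formats the pipeline touches.

Formats: a plain marker x sample logR TSV, a minimal GenomeStudio
Final-Report dialect ([Header]/[Data] sections, long format), BED (0-based
half-open), GMT gene-set collections, tab-delimited QTL tables with a trait
class column, CNV call / trajectory tables and JSON summaries.

Chromosome labels are normalized on ingestion by stripping a leading "chr";
BED export restores the prefix.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import Feature
from .segmentation import CnvCall
from .sim import MarkerMap, TruthCnv
from .temporal import CnvTrajectory

__all__ = [
    "ParseError",
    "normalize_chrom",
    "read_final_report",
    "write_final_report",
    "read_logr_tsv",
    "write_logr_tsv",
    "read_bed",
    "write_bed",
    "read_gmt",
    "read_qtl_table",
    "read_gene_features",
    "write_calls_tsv",
    "read_calls_tsv",
    "write_trajectories_tsv",
    "write_truth",
    "write_json_summary",
]

FINAL_REPORT_COLUMNS = ["Sample ID", "SNP Name", "Chr", "Position", "Log R Ratio"]


class ParseError(ValueError):
    """Malformed input file; message carries file context."""


def normalize_chrom(label: str) -> str:
    label = str(label).strip()
    return label[3:] if label.lower().startswith("chr") else label


def _chrom_sort_key(label: str):
    return (0, int(label)) if label.isdigit() else (1, label)


# ---------------------------------------------------------------- logR

def read_final_report(path: str | Path) -> tuple[pd.DataFrame, MarkerMap]:
    """Read a GenomeStudio Final-Report-style export.

    The file holds an optional ``[Header]`` section followed by ``[Data]``
    and a tab-delimited table with at least the columns Sample ID, SNP Name,
    Chr, Position, Log R Ratio. Returns one track per sample aligned to a
    map sorted by (chromosome, position); missing logR entries become NaN.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    start = 0
    for i, line in enumerate(lines):
        if line.strip() == "[Data]":
            start = i + 1
            break
    if start == 0 and lines and lines[0].strip() == "[Header]":
        raise ParseError(f"{path}: [Header] present but no [Data] section")
    header = lines[start].split("\t")
    missing = [c for c in FINAL_REPORT_COLUMNS if c not in header]
    if missing:
        raise ParseError(f"{path}: missing mandatory column(s) {missing}")
    df = pd.read_csv(
        path,
        sep="\t",
        skiprows=start,
        dtype={"Chr": str, "SNP Name": str, "Sample ID": str},
    )
    df["Chr"] = df["Chr"].map(normalize_chrom)
    markers = (
        df[["SNP Name", "Chr", "Position"]]
        .drop_duplicates()
        .rename(columns={"SNP Name": "marker_id", "Chr": "chromosome", "Position": "position"})
    )
    if markers["marker_id"].duplicated().any():
        dups = markers.loc[markers["marker_id"].duplicated(), "marker_id"].tolist()
        raise ParseError(f"{path}: conflicting coordinates for markers {dups[:5]}")
    markers = markers.sort_values(
        by=["chromosome", "position"],
        key=lambda s: s.map(_chrom_sort_key) if s.name == "chromosome" else s,
    ).reset_index(drop=True)
    samples = sorted(set(df["Sample ID"]))  # canonical sample order
    per_sample_markers = df.groupby("Sample ID")["SNP Name"].apply(set)
    full = set(markers["marker_id"])
    bad = {s: sorted(full - ms)[:5] for s, ms in per_sample_markers.items() if ms != full}
    if bad:
        raise ParseError(f"{path}: inconsistent marker sets across samples: {bad}")
    wide = df.pivot_table(
        index="SNP Name", columns="Sample ID", values="Log R Ratio", aggfunc="first"
    )
    wide = wide.reindex(markers["marker_id"])[samples].reset_index(drop=True)
    wide.columns.name = None
    marker_map = MarkerMap(markers[["chromosome", "position", "marker_id"]])
    return wide, marker_map


def write_final_report(
    tracks: pd.DataFrame, marker_map: MarkerMap, path: str | Path
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("[Header]\n")
        fh.write("GSGT Version\tsynthetic\n")
        fh.write(f"Num SNPs\t{marker_map.n_markers}\n")
        fh.write(f"Num Samples\t{len(tracks.columns)}\n")
        fh.write("[Data]\n")
        fh.write("\t".join(FINAL_REPORT_COLUMNS) + "\n")
        mm = marker_map.df
        for sample in tracks.columns:
            values = tracks[sample].to_numpy()
            for i in range(marker_map.n_markers):
                fh.write(
                    f"{sample}\t{mm.marker_id.iat[i]}\t{mm.chromosome.iat[i]}\t"
                    f"{mm.position.iat[i]}\t{values[i]:.4f}\n"
                )


def read_logr_tsv(path: str | Path) -> tuple[pd.DataFrame, MarkerMap]:
    """Read the plain marker x sample matrix written by ``write_logr_tsv``."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    for col in ("chromosome", "position", "marker_id"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    df["chromosome"] = df["chromosome"].map(normalize_chrom)
    marker_map = MarkerMap(df[["chromosome", "position", "marker_id"]].copy())
    tracks = df.drop(columns=["chromosome", "position", "marker_id"])
    return tracks, marker_map


def write_logr_tsv(
    tracks: pd.DataFrame, marker_map: MarkerMap, path: str | Path
) -> None:
    out = pd.concat([marker_map.df.reset_index(drop=True), tracks.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------- intervals

def read_bed(path: str | Path, kind: str = "gene") -> list[Feature]:
    """Read BED intervals (0-based half-open) as features.

    Column 4, when present, is the feature name. Malformed lines are
    reported with their line numbers; an empty file yields an empty list.
    """
    features: list[Feature] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 3:
            raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
        if end <= start:
            raise ParseError(f"{path}:{lineno}: end must exceed start")
        name = parts[3] if len(parts) > 3 else f"feature_{lineno}"
        features.append(
            Feature(normalize_chrom(parts[0]), start, end, name, kind=kind)
        )
    return features


def write_bed(
    intervals: Iterable[tuple[str, int, int, str]], path: str | Path, chr_prefix: bool = True
) -> None:
    with Path(path).open("w") as fh:
        for chrom, start, end, name in intervals:
            label = f"chr{chrom}" if chr_prefix and not str(chrom).startswith("chr") else chrom
            fh.write(f"{label}\t{start}\t{end}\t{name}\n")


def read_gmt(path: str | Path) -> dict[str, set]:
    """Read a GMT gene-set collection: one set per line, tab-delimited
    ``name <tab> description <tab> member...``."""
    sets: dict[str, set] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}:{lineno}: GMT line needs name, description, members")
        sets[parts[0]] = set(parts[2:])
    return sets


def read_qtl_table(path: str | Path) -> list[Feature]:
    """Read a tab-delimited QTL table with header columns
    chromosome, start_bp, end_bp, name, trait_class."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    required = {"chromosome", "start_bp", "end_bp", "name", "trait_class"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    return [
        Feature(
            normalize_chrom(r.chromosome),
            int(r.start_bp),
            int(r.end_bp),
            str(r.name),
            kind="qtl",
            trait_class=str(r.trait_class),
        )
        for r in df.itertuples(index=False)
    ]


def read_gene_features(path: str | Path) -> list[Feature]:
    """Genes as BED or as a RefSeq-style TSV with header columns
    chromosome, start_bp, end_bp, name."""
    first = Path(path).read_text().splitlines()
    header = first[0].split("\t") if first else []
    if {"chromosome", "start_bp", "end_bp", "name"} <= set(header):
        df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
        return [
            Feature(normalize_chrom(r.chromosome), int(r.start_bp), int(r.end_bp), str(r.name))
            for r in df.itertuples(index=False)
        ]
    return read_bed(path, kind="gene")


# ---------------------------------------------------------------- tables

_CALL_COLUMNS = [
    "cnv_id", "sample_id", "time_point", "chromosome",
    "start_bp", "end_bp", "n_markers", "mean_logr", "state",
]


def write_calls_tsv(calls: Sequence[CnvCall], path: str | Path) -> None:
    rows = [{c: getattr(call, c) for c in _CALL_COLUMNS} for call in calls]
    pd.DataFrame(rows, columns=_CALL_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def read_calls_tsv(path: str | Path) -> list[CnvCall]:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str, "sample_id": str})
    missing = set(_CALL_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    return [
        CnvCall(
            sample_id=str(r.sample_id),
            time_point=int(r.time_point),
            chromosome=normalize_chrom(r.chromosome),
            start_bp=int(r.start_bp),
            end_bp=int(r.end_bp),
            n_markers=int(r.n_markers),
            mean_logr=float(r.mean_logr),
            state=str(r.state),
            cnv_id=str(r.cnv_id),
        )
        for r in df.itertuples(index=False)
    ]


def write_trajectories_tsv(trajectories: Sequence[CnvTrajectory], path: str | Path) -> None:
    rows = []
    for t in trajectories:
        rows.append(
            {
                "subject_id": t.subject_id,
                "chromosome": t.chromosome,
                "merged_start_bp": t.merged_start_bp,
                "merged_end_bp": t.merged_end_bp,
                "state": t.state,
                "presence_pattern": "".join("1" if x else "0" for x in t.presence_pattern),
                "temporal_class": t.temporal_class,
                "member_call_ids": ",".join(t.member_call_ids),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_truth(
    truth: Sequence[TruthCnv], marker_map: MarkerMap, bed_path: str | Path, tsv_path: str | Path
) -> None:
    """Truth CNVs as BED (0-based half-open bp intervals) plus a TSV sidecar
    with subject, state and presence pattern."""
    positions = marker_map.positions()
    bed_rows = []
    tsv_rows = []
    for i, t in enumerate(truth):
        start = int(positions[t.start_marker_index]) - 1
        end = int(positions[t.end_marker_index])
        name = f"truth_{i + 1}"
        bed_rows.append((t.chromosome, start, end, name))
        tsv_rows.append(
            {
                "name": name,
                "subject_id": t.subject_id,
                "chromosome": t.chromosome,
                "start_marker_index": t.start_marker_index,
                "end_marker_index": t.end_marker_index,
                "state": t.state,
                "mean_shift": t.mean_shift,
                "presence_pattern": "".join("1" if x else "0" for x in t.presence_pattern),
            }
        )
    write_bed(bed_rows, bed_path)
    pd.DataFrame(tsv_rows).to_csv(tsv_path, sep="\t", index=False)


def write_json_summary(summary: dict, path: str | Path) -> None:
    def _default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True, default=_default) + "\n")
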