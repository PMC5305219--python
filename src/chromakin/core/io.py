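"""Readers and writers for the flat-file formats the pipeline consumes.

Formats: BED6, narrowPeak (BED6+4 with MACS fold enrichment, q-value and
summit offset), bedGraph, GTF (gene/exon features only), FASTA, TSV count
matrices and sample sheets. All writers emit files their readers accept;
round-trips are lossless on canonicalized records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .intervals import CoordinateError, GenomicInterval, GeneModel

log = logging.getLogger(__name__)


class ParseError(ValueError):
    """Malformed input line; message carries the file and line number."""


# ---------------------------------------------------------------------------
# Peaks (narrowPeak: BED6 + signalValue, pValue, qValue, summit offset)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Peak:
    interval: GenomicInterval
    summit: int  # absolute position
    fold_enrichment: float
    qvalue: float  # -log10 as in narrowPeak column 9
    condition: str = ""
    name: str = "."

    def __post_init__(self) -> None:
        if not self.interval.contains(self.summit):
            raise CoordinateError(f"summit {self.summit} outside {self.interval}")
        if self.fold_enrichment <= 0:
            raise CoordinateError(f"fold_enrichment <= 0 in {self.name}")


def read_peaks(path: str | Path, condition: str = "") -> list[Peak]:
    peaks: list[Peak] = []
    for lineno, fields in _rows(path, ncols=10):
        try:
            iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]), fields[5])
            peaks.append(
                Peak(
                    interval=iv,
                    summit=iv.start + int(fields[9]),
                    fold_enrichment=float(fields[6]),
                    qvalue=float(fields[8]),
                    condition=condition,
                    name=fields[3],
                )
            )
        except (ValueError, CoordinateError) as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def write_peaks(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t0\t{iv.strand}\t"
                f"{p.fold_enrichment:g}\t-1\t{p.qvalue:g}\t{p.summit - iv.start}\n"
            )


# ---------------------------------------------------------------------------
# BED6 (generic intervals, e.g. repeats, anchors, reads)
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    for lineno, fields in _rows(path, ncols=3):
        strand = fields[5] if len(fields) >= 6 else "."
        try:
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand))
        except (ValueError, CoordinateError) as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path, names: Iterable[str] | None = None) -> None:
    names = list(names) if names is not None else None
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Coverage (bedGraph <-> per-base arrays)
# ---------------------------------------------------------------------------


@dataclass
class CoverageTrack:
    """Per-base read depth per chromosome, with a normalization factor."""

    depth: dict[str, np.ndarray]
    factor: float = 1.0

    def chrom_length(self, chrom: str) -> int:
        return len(self.depth[chrom])

    def total(self) -> float:
        return float(sum(arr.sum() for arr in self.depth.values()))


def read_coverage(path: str | Path, chrom_lengths: Mapping[str, int]) -> CoverageTrack:
    """Parse a bedGraph into dense per-base arrays.

    Overlapping records are a validation error: a bedGraph assigns one value
    per base.
    """
    depth = {c: np.zeros(n, dtype=np.float64) for c, n in chrom_lengths.items()}
    seen_end: dict[str, int] = {}
    frame = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": np.float64},
    )
    for chrom, sub in frame.groupby("chrom", sort=False):
        if chrom not in depth:
            raise ParseError(f"{path}: unknown chromosome {chrom!r}")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        order = np.argsort(starts, kind="stable")
        starts, ends = starts[order], ends[order]
        vals = sub["value"].to_numpy()[order]
        if np.any(ends <= starts) or starts[0] < 0 or ends[-1] > len(depth[chrom]):
            raise ParseError(f"{path}: bad coordinates on {chrom}")
        if np.any(starts[1:] < ends[:-1]):
            raise ParseError(f"{path}: overlapping bedGraph records on {chrom}")
        diff = np.zeros(len(depth[chrom]) + 1)
        np.add.at(diff, starts, vals)
        np.add.at(diff, ends, -vals)
        depth[chrom] = np.cumsum(diff)[:-1]
        seen_end[chrom] = int(ends[-1])
    return CoverageTrack(depth=depth)


def write_coverage(track: CoverageTrack, path: str | Path, precision: int = 6) -> None:
    """Write dense depth as run-length-collapsed bedGraph (zero runs skipped)."""
    with open(path, "w") as fh:
        for chrom in sorted(track.depth):
            arr = track.depth[chrom]
            if len(arr) == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v == 0:
                    continue
                fh.write(f"{chrom}\t{s}\t{e}\t{round(float(v), precision):g}\n")


# ---------------------------------------------------------------------------
# Gene models (GTF gene/exon features, 1-based closed -> 0-based half-open)
# ---------------------------------------------------------------------------


def read_gene_models(path: str | Path) -> list[GeneModel]:
    genes: dict[str, GenomicInterval] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    order: list[str] = []
    for lineno, fields in _rows(path, ncols=9):
        feature = fields[2]
        if feature not in ("gene", "exon"):
            continue
        try:
            iv = GenomicInterval(fields[0], int(fields[3]) - 1, int(fields[4]), fields[6])
            gid = _gtf_attr(fields[8], "gene_id")
        except (ValueError, CoordinateError) as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        if gid is None:
            raise ParseError(f"{path}:{lineno}: missing gene_id attribute")
        if feature == "gene":
            genes[gid] = iv
            order.append(gid)
        else:
            exons.setdefault(gid, []).append(iv)
    out = []
    for gid in order:
        try:
            out.append(GeneModel(gid, genes[gid], tuple(sorted(exons.get(gid, []), key=lambda e: e.start))))
        except CoordinateError as exc:
            raise ParseError(f"{path}: gene {gid}: {exc}") from exc
    return out


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{iv.chrom}\tchromakin\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n"
            )
            for ex in g.exons:
                fh.write(
                    f"{ex.chrom}\tchromakin\texon\t{ex.start + 1}\t{ex.end}\t.\t{iv.strand}\t.\t{attrs}\n"
                )


def _gtf_attr(attr_field: str, key: str) -> str | None:
    for chunk in attr_field.split(";"):
        chunk = chunk.strip()
        if chunk.startswith(key):
            return chunk[len(key):].strip().strip('"')
    return None


# ---------------------------------------------------------------------------
# Count matrices and sample sheets
# ---------------------------------------------------------------------------

ASSAYS = ("RNA", "SMAD2", "PolII-Ser5P", "PolII-Ser2P", "H3K9Ac", "H3K27Ac", "H3", "input")
CONDITIONS = ("SB", "Activin1h", "Activin8h", "Untreated")


def read_counts(path: str | Path) -> pd.DataFrame:
    """Genes x samples matrix; first column gene_id, header = sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ParseError(f"{path}: duplicate gene ids")
    if (df.to_numpy() < 0).any():
        raise ParseError(f"{path}: negative counts")
    return df


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Columns: sample_id, assay, condition, replicate[, treatment]."""
    df = pd.read_csv(path, sep="\t", dtype={"replicate": int})
    required = {"sample_id", "assay", "condition", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    bad_assay = set(df["assay"]) - set(ASSAYS)
    if bad_assay:
        raise ParseError(f"{path}: unknown assays {sorted(bad_assay)}")
    bad_cond = set(df["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise ParseError(f"{path}: unknown conditions {sorted(bad_cond)}")
    key = df[["assay", "condition", "replicate"]]
    if "treatment" in df.columns:
        key = df[["assay", "condition", "replicate", "treatment"]]
    if key.duplicated().any():
        raise ParseError(f"{path}: duplicate (assay, condition, replicate)")
    return df


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------


def _rows(path: str | Path, ncols: int):
    """Yield (lineno, fields) for tab-separated lines, skipping comments."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < ncols:
                raise ParseError(f"{path}:{lineno}: expected >= {ncols} columns, got {len(fields)}")
            yield lineno, fields
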