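"""SMAD2 peak processing: fold-enrichment and repeat filtering, consensus
construction by single-nucleotide overlap, annotation, normalized
quantification, peak-to-gene association and the per-gene binding footprint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core.intervals import (
    GeneModel,
    GenomicInterval,
    merge_intervals,
    nearest_gene_distance,
    overlap_length,
)
from .core.io import Peak

log = logging.getLogger(__name__)

FOLD_ENRICHMENT_MIN = 3.0
REPEAT_OVERLAP_MAX = 0.5
ASSOCIATION_MAX_DISTANCE = 100_000
TARGET_LIBRARY = 40_000_000
READ_SHIFT = 100  # half the 200-bp fragment
TSS_WINDOW = 500


@dataclass
class ConsensusPeak:
    interval: GenomicInterval
    members: list[Peak]
    peak_id: str = ""
    annotation: str = ""
    gene_id: str | None = None
    norm_counts: dict[str, float] = field(default_factory=dict)
    has_foxh1_motif: bool | None = None

    @property
    def avg_summit(self) -> int:
        """Arithmetic mean of member summits, rounded to an integer base."""
        return int(round(np.mean([m.summit for m in self.members])))

    @property
    def conditions(self) -> set[str]:
        return {m.condition for m in self.members}


def filter_peaks(
    peaks: list[Peak],
    repeats: list[GenomicInterval] | None = None,
    min_fold: float = FOLD_ENRICHMENT_MIN,
    max_repeat_fraction: float = REPEAT_OVERLAP_MAX,
) -> list[Peak]:
    """Drop peaks with fold enrichment < 3.0 and peaks lying mostly
    (overlap fraction >= 0.5 by default) in annotated repeats."""
    kept = [p for p in peaks if p.fold_enrichment >= min_fold]
    if not repeats:
        return kept
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for r in repeats:
        by_chrom.setdefault(r.chrom, []).append(r)
    for c in by_chrom:
        by_chrom[c].sort(key=lambda iv: iv.start)
    out = []
    for p in kept:
        cov = _covered_bases(p.interval, by_chrom.get(p.interval.chrom, []))
        if cov / len(p.interval) < max_repeat_fraction:
            out.append(p)
    return out


def _covered_bases(iv: GenomicInterval, sorted_track: list[GenomicInterval]) -> int:
    """Bases of iv covered by the union of a sorted interval track."""
    covered = 0
    cursor = iv.start
    for r in sorted_track:
        if r.end <= cursor:
            continue
        if r.start >= iv.end:
            break
        covered += min(r.end, iv.end) - max(r.start, cursor)
        cursor = max(cursor, min(r.end, iv.end))
    return covered


def build_consensus(peaks: list[Peak]) -> list[ConsensusPeak]:
    """Merge peaks sharing >= 1 bp (transitive closure) into consensus loci."""
    merged = merge_intervals([p.interval for p in peaks])
    out = []
    for i, (iv, member_idx) in enumerate(merged):
        members = [peaks[j] for j in member_idx]
        out.append(ConsensusPeak(interval=iv, members=members, peak_id=f"cp{i + 1:05d}"))
    return out


ANNOTATION_LABELS = ("TSS", "exonic", "intronic", "upstream_intergenic", "downstream_intergenic")


def annotate_peak(cp: ConsensusPeak, genes: list[GeneModel], tss_window: int = TSS_WINDOW) -> str:
    """Classify a consensus peak by its average summit.

    Precedence: TSS (+/- 500 bp) > exonic > intronic > intergenic, the last
    split up-/downstream relative to the nearest gene's strand.
    """
    if not genes:
        raise ValueError("empty gene set")
    summit = cp.avg_summit
    chrom = cp.interval.chrom
    same_chrom = [g for g in genes if g.interval.chrom == chrom]
    for g in same_chrom:
        if abs(summit - g.tss) <= tss_window:
            return "TSS"
    in_exon = in_gene = False
    for g in same_chrom:
        if g.interval.contains(summit):
            in_gene = True
            if any(e.contains(summit) for e in g.exons):
                in_exon = True
                break
    if in_exon:
        return "exonic"
    if in_gene:
        return "intronic"
    nearest = min(
        same_chrom,
        key=lambda g: nearest_gene_distance(chrom, summit, g),
        default=None,
    )
    if nearest is None:
        raise ValueError(f"no gene on chromosome {chrom}")
    before = summit < nearest.interval.start
    if nearest.strand == "+":
        return "upstream_intergenic" if before else "downstream_intergenic"
    return "downstream_intergenic" if before else "upstream_intergenic"


def shifted_read_positions(reads, shift: int = READ_SHIFT) -> dict[str, np.ndarray]:
    """5' read positions shifted `shift` bp toward 3' (fragment-center proxy).

    Accepts a list of GenomicInterval or a DataFrame with columns
    chrom/start/end/strand (the fast path for large read sets).
    """
    if isinstance(reads, pd.DataFrame):
        plus = reads["strand"].to_numpy() != "-"
        pos = np.where(plus, reads["start"].to_numpy() + shift, reads["end"].to_numpy() - 1 - shift)
        out = {}
        for chrom, sub in pd.Series(pos).groupby(reads["chrom"].to_numpy()):
            out[str(chrom)] = np.sort(sub.to_numpy().astype(np.int64))
        return out
    pos_by: dict[str, list[int]] = {}
    for r in reads:
        p = r.start + shift if r.oriented_strand() == "+" else r.end - 1 - shift
        pos_by.setdefault(r.chrom, []).append(p)
    return {c: np.sort(np.array(v, dtype=np.int64)) for c, v in pos_by.items()}


def normalized_peak_counts(
    positions: dict[str, np.ndarray],
    total_mapped: int,
    consensus: list[ConsensusPeak],
    sample_id: str,
    target_library: int = TARGET_LIBRARY,
) -> None:
    """Count shifted-read positions per consensus interval, scaled so the
    library totals 40e6 mapped reads; stored under sample_id on each peak."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    scale = target_library / total_mapped
    for cp in consensus:
        arr = positions.get(cp.interval.chrom)
        if arr is None:
            cp.norm_counts[sample_id] = 0.0
            continue
        lo = np.searchsorted(arr, cp.interval.start, side="left")
        hi = np.searchsorted(arr, cp.interval.end, side="left")
        cp.norm_counts[sample_id] = float(hi - lo) * scale


def associate_peaks(
    consensus: list[ConsensusPeak],
    regulated_genes: list[GeneModel],
    max_distance: int = ASSOCIATION_MAX_DISTANCE,
) -> None:
    """Assign each consensus peak to the closest regulated gene by
    min(|summit-TSS|, |summit-TTS|) (0 inside the gene body); peaks farther
    than 100 kb from every regulated gene stay unassigned."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in regulated_genes:
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    for cp in consensus:
        summit = cp.avg_summit
        best, best_d = None, None
        for g in by_chrom.get(cp.interval.chrom, []):
            d = nearest_gene_distance(cp.interval.chrom, summit, g)
            if best_d is None or d < best_d or (d == best_d and g.gene_id < best.gene_id):
                best, best_d = g, d
        cp.gene_id = best.gene_id if best is not None and best_d <= max_distance else None


def smad2_footprint(
    consensus: list[ConsensusPeak],
    sheet: pd.DataFrame,
    reference: str = "SB",
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-gene, per-condition footprint: sum over associated consensus peaks
    of the replicate-averaged normalized counts; log2FC vs SB with
    pseudocount. Genes without peaks get footprint 0 and log2fc NA."""
    smad = sheet[sheet["assay"] == "SMAD2"]
    cond_samples = {c: sub["sample_id"].tolist() for c, sub in smad.groupby("condition")}
    rows: dict[str, dict[str, float]] = {}
    for cp in consensus:
        if cp.gene_id is None:
            continue
        row = rows.setdefault(cp.gene_id, {c: 0.0 for c in cond_samples})
        for cond, samples in cond_samples.items():
            row[cond] += float(np.mean([cp.norm_counts.get(s, 0.0) for s in samples]))
    if not rows:
        cols = list(cond_samples) + [f"log2fc_{c}" for c in cond_samples if c != reference]
        empty = pd.DataFrame(columns=cols)
        empty.index.name = "gene_id"
        return empty
    frame = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    frame.index.name = "gene_id"
    for cond in cond_samples:
        if cond == reference:
            continue
        frame[f"log2fc_{cond}"] = np.log2(
            (frame[cond] + pseudocount) / (frame[reference] + pseudocount)
        )
    return frame


def peak_density_profile(
    consensus: list[ConsensusPeak],
    genes: dict[str, GeneModel],
    model_length: int = 20_000,
    window: int = 100_000,
    binsize: int = 1_000,
) -> pd.DataFrame:
    """Summit density over a modeled gene coordinate system.

    Every associated gene is rescaled so its body spans [0, 20 kb) in the 5'
    to 3' direction; up-/downstream offsets are preserved in real bases.
    Returns bin left edges (relative to the modeled TSS at 0) and counts.
    """
    coords = []
    for cp in consensus:
        if cp.gene_id is None or cp.gene_id not in genes:
            continue
        g = genes[cp.gene_id]
        s = cp.avg_summit
        start, end = g.interval.start, g.interval.end
        glen = end - start
        if g.strand == "+":
            if s < start:
                coord = s - start
            elif s >= end:
                coord = model_length + (s - end + 1)
            else:
                coord = (s - start) / glen * model_length
        else:
            if s >= end:
                coord = -(s - end + 1)
            elif s < start:
                coord = model_length + (start - s)
            else:
                coord = (end - 1 - s) / glen * model_length
        if -window <= coord <= model_length + window:
            coords.append(coord)
    edges = np.arange(-window, model_length + window + binsize, binsize)
    hist, _ = np.histogram(coords, bins=edges)
    return pd.DataFrame({"bin_start": edges[:-1], "count": hist})


def consensus_frame(consensus: list[ConsensusPeak]) -> pd.DataFrame:
    """Flat table of consensus peaks (for TSV export)."""
    rows = []
    for cp in consensus:
        row = {
            "peak_id": cp.peak_id,
            "chrom": cp.interval.chrom,
            "start": cp.interval.start,
            "end": cp.interval.end,
            "avg_summit": cp.avg_summit,
            "n_members": len(cp.members),
            "conditions": ",".join(sorted(cp.conditions)),
            "annotation": cp.annotation,
            "gene_id": cp.gene_id if cp.gene_id is not None else "",
        }
        row.update({f"norm_{k}": v for k, v in sorted(cp.norm_counts.items())})
        rows.append(row)
    return pd.DataFrame(rows)
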