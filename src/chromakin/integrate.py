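"""High-confidence target-gene construction: the intersection of the
RNA-differential and Pol II-differential gene lists, with outliers on either
side rescued by a replicate-conserved SMAD2 peak within 100 kb of the TSS or
TTS, plus the final per-gene master table."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core.intervals import GeneModel, GenomicInterval, nearest_gene_distance
from .core.io import Peak
from .peaks import ConsensusPeak, ASSOCIATION_MAX_DISTANCE

log = logging.getLogger(__name__)


def replicate_conserved_peaks(
    rep1: list[Peak], rep2: list[Peak]
) -> list[GenomicInterval]:
    """Peaks conserved between the two biological replicates, operationalized
    as >= 1-bp overlap; returns the rep1 intervals that have a rep2 partner."""
    by_chrom: dict[str, list[Peak]] = {}
    for p in rep2:
        by_chrom.setdefault(p.interval.chrom, []).append(p)
    out = []
    for p in rep1:
        for q in by_chrom.get(p.interval.chrom, []):
            if p.interval.overlaps(q.interval):
                out.append(p.interval)
                break
    return out


def _has_conserved_peak_nearby(
    gene: GeneModel,
    conserved: list[GenomicInterval],
    max_distance: int = ASSOCIATION_MAX_DISTANCE,
) -> bool:
    for iv in conserved:
        if iv.chrom != gene.interval.chrom:
            continue
        mid = (iv.start + iv.end) // 2
        if nearest_gene_distance(iv.chrom, mid, gene) <= max_distance:
            return True
    return False


def build_high_confidence(
    de_genes: set[str],
    polii_genes: set[str],
    genes: dict[str, GeneModel],
    conserved_peaks: list[GenomicInterval],
    max_distance: int = ASSOCIATION_MAX_DISTANCE,
) -> pd.DataFrame:
    """Core = DE ∩ Pol II; rescue = genes in exactly one list with a
    replicate-conserved SMAD2 peak within 100 kb of TSS/TTS."""
    core = de_genes & polii_genes
    rows = []
    for gid in sorted(de_genes | polii_genes):
        evidence = []
        if gid in de_genes:
            evidence.append("rna_de")
        if gid in polii_genes:
            evidence.append("polii_diff")
        if gid in core:
            rows.append((gid, ",".join(evidence)))
            continue
        gene = genes.get(gid)
        if gene is None:
            log.warning("gene %s has no model; cannot test peak rescue", gid)
            continue
        if _has_conserved_peak_nearby(gene, conserved_peaks, max_distance):
            evidence.append("rescued_by_replicated_peak")
            rows.append((gid, ",".join(evidence)))
    frame = pd.DataFrame(rows, columns=["gene_id", "evidence"]).set_index("gene_id")
    return frame.sort_index()


def summarize(
    high_confidence: pd.DataFrame,
    kinetic_calls: pd.DataFrame | None = None,
    footprints: pd.DataFrame | None = None,
    polii_lfc: pd.DataFrame | None = None,
    consensus: list[ConsensusPeak] | None = None,
) -> pd.DataFrame:
    """Master table: one row per high-confidence gene, deterministic gene_id
    order, NA where an upstream stage carries no value for the gene."""
    out = high_confidence.copy()
    if kinetic_calls is not None:
        for col in ("category", "baseline", "directness"):
            out[col] = kinetic_calls[col].reindex(out.index)
    if footprints is not None:
        for col in footprints.columns:
            out[f"footprint_{col}"] = footprints[col].reindex(out.index)
    if polii_lfc is not None:
        for col in polii_lfc.columns:
            if col.startswith("log2fc_"):
                out[f"polii_{col}"] = polii_lfc[col].reindex(out.index)
    if consensus is not None:
        peak_map: dict[str, list[str]] = {}
        anno_map: dict[str, list[str]] = {}
        for cp in consensus:
            if cp.gene_id is not None:
                peak_map.setdefault(cp.gene_id, []).append(cp.peak_id)
                if cp.annotation:
                    anno_map.setdefault(cp.gene_id, []).append(cp.annotation)
        out["peak_ids"] = [",".join(peak_map.get(g, [])) for g in out.index]
        out["peak_annotations"] = [",".join(anno_map.get(g, [])) for g in out.index]
    return out.sort_index()
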