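"""ChIP normalization factors from high-signal/low-variance bins, the
SB geometric-mean harmonization across comparisons of one IP, windowed
differential-occupancy calling against SB, and gene-level calls via the
differential-base overlap ratio."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core.intervals import GeneModel, GenomicInterval
from .core.io import CoverageTrack
from .de import bh_adjust, pooled_dispersion, PSEUDOCOUNT, LN2
from scipy import stats

log = logging.getLogger(__name__)

OVERLAP_RATIO_CUTOFF = 0.09
GENE_FLANK = 2_000
WINDOW = 1_000
STEP = 100
FRAGMENT_LENGTH = 200
Q_CUTOFF = 0.05


class NormalizationError(ValueError):
    pass


def bin_matrix(tracks: dict[str, CoverageTrack], binsize: int = 1_000) -> pd.DataFrame:
    """Mean depth per genomic bin (rows) per sample (columns)."""
    sample_ids = list(tracks)
    chroms = sorted(next(iter(tracks.values())).depth)
    cols = {s: [] for s in sample_ids}
    index = []
    for chrom in chroms:
        n = len(next(iter(tracks.values())).depth[chrom])
        nbins = n // binsize
        for s in sample_ids:
            arr = tracks[s].depth[chrom][: nbins * binsize]
            cols[s].append(arr.reshape(nbins, binsize).mean(axis=1))
        index.extend(f"{chrom}:{i * binsize}" for i in range(nbins))
    return pd.DataFrame({s: np.concatenate(cols[s]) for s in sample_ids}, index=index)


def normalization_factors(
    tracks: dict[str, CoverageTrack],
    binsize: int = 1_000,
    signal_percentile: float = 90.0,
    min_bins: int = 10,
) -> pd.Series:
    """Per-sample factors from bins with high signal and low cross-sample
    variance: bins whose cross-sample mean depth is above the 90th
    percentile and whose coefficient of variation is below the median CV of
    that high-signal subset; factors are median-of-ratios over those bins."""
    if len(tracks) < 2:
        raise NormalizationError("need >= 2 samples")
    bins = bin_matrix(tracks, binsize)
    mean = bins.mean(axis=1)
    cutoff = np.percentile(mean, signal_percentile)
    high = bins[mean >= cutoff]
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = high.std(axis=1, ddof=1) / high.mean(axis=1)
    stable = high[cv <= cv.median()]
    if len(stable) < min_bins:
        raise NormalizationError(f"only {len(stable)} stable bins selected")
    mat = stable.to_numpy(dtype=float)
    nonzero = (mat > 0).all(axis=1)
    mat = mat[nonzero]
    if len(mat) < min_bins:
        raise NormalizationError("too few all-nonzero stable bins")
    log_geo = np.mean(np.log(mat), axis=1, keepdims=True)
    factors = np.median(np.exp(np.log(mat) - log_geo), axis=0)
    return pd.Series(factors, index=bins.columns, name="factor")


def harmonize_sb_geomean(
    factors_per_comparison: dict[str, pd.Series],
    sb_samples: dict[str, list[str]],
) -> dict[str, pd.Series]:
    """Rescale each comparison's factors so the geometric mean of its SB
    samples equals that of the first (reference) comparison. Within-
    comparison ratios are preserved exactly."""
    comparisons = list(factors_per_comparison)
    ref = comparisons[0]
    ref_geo = float(stats.gmean(factors_per_comparison[ref][sb_samples[ref]]))
    out = {}
    for comp in comparisons:
        geo = float(stats.gmean(factors_per_comparison[comp][sb_samples[comp]]))
        out[comp] = factors_per_comparison[comp] / (geo / ref_geo)
    return out


@dataclass(frozen=True)
class DifferentialRegion:
    interval: GenomicInterval
    direction: str  # up | down
    statistic: float
    qvalue: float


def call_differential_windows(
    treat_tracks: dict[str, CoverageTrack],
    ref_tracks: dict[str, CoverageTrack],
    factors: pd.Series,
    window: int = WINDOW,
    step: int = STEP,
    fragment_length: int = FRAGMENT_LENGTH,
    q_cutoff: float = Q_CUTOFF,
) -> list[DifferentialRegion]:
    """Sliding-window (1 kb, 100-bp step) NB test of treatment vs SB.

    Window statistics are approximate fragment counts (depth sum divided by
    the fragment length), factor-normalized. Significant (q < 0.05)
    same-direction overlapping windows are merged into regions.
    """
    if len(treat_tracks) < 2 or len(ref_tracks) < 2:
        raise ValueError("need >= 2 replicates per group")
    chroms = sorted(next(iter(treat_tracks.values())).depth)
    all_counts, meta = [], []
    for chrom in chroms:
        n = len(next(iter(treat_tracks.values())).depth[chrom])
        starts = np.arange(0, max(n - window, 0) + 1, step)
        if len(starts) == 0:
            continue
        cum = {}
        for s, tr in {**treat_tracks, **ref_tracks}.items():
            c = np.concatenate(([0.0], np.cumsum(tr.depth[chrom])))
            cum[s] = c
        wins = np.stack(
            [
                (cum[s][starts + window] - cum[s][starts]) / fragment_length / factors[s]
                for s in list(treat_tracks) + list(ref_tracks)
            ],
            axis=1,
        )
        all_counts.append(wins)
        meta.extend((chrom, int(st)) for st in starts)
    if not all_counts:
        return []
    mat = np.concatenate(all_counts, axis=0)
    nt, nr = len(treat_tracks), len(ref_tracks)
    a_idx = np.arange(nt)
    b_idx = np.arange(nt, nt + nr)
    disp = pooled_dispersion(mat, [a_idx, b_idx])
    mA = mat[:, a_idx].mean(axis=1)
    mB = mat[:, b_idx].mean(axis=1)
    lfc = np.log2((mA + PSEUDOCOUNT) / (mB + PSEUDOCOUNT))
    varA = (mA + disp * mA**2) / nt / (mA + PSEUDOCOUNT) ** 2
    varB = (mB + disp * mB**2) / nr / (mB + PSEUDOCOUNT) ** 2
    se = np.sqrt(varA + varB)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc * LN2 / se, 0.0)
    pval = 2.0 * stats.norm.sf(np.abs(z))
    pval[(mA == 0) & (mB == 0)] = 1.0
    qval = bh_adjust(pval)
    sig = qval < q_cutoff

    regions: list[DifferentialRegion] = []
    current = None  # [chrom, start, end, direction, max|z|, min q]
    for i in np.flatnonzero(sig):
        chrom, start = meta[i]
        direction = "up" if lfc[i] > 0 else "down"
        end = start + window
        if (
            current is not None
            and current[0] == chrom
            and current[3] == direction
            and start < current[2]
        ):
            current[2] = max(current[2], end)
            current[4] = max(current[4], abs(z[i]))
            current[5] = min(current[5], qval[i])
        else:
            if current is not None:
                regions.append(_region(current))
            current = [chrom, start, end, direction, abs(z[i]), qval[i]]
    if current is not None:
        regions.append(_region(current))
    return regions


def _region(c) -> DifferentialRegion:
    return DifferentialRegion(
        interval=GenomicInterval(c[0], c[1], c[2]),
        direction=c[3],
        statistic=float(c[4]),
        qvalue=float(c[5]),
    )


def gene_overlap_ratio(
    regions: list[DifferentialRegion],
    gene: GeneModel,
    flank: int = GENE_FLANK,
    cutoff: float = OVERLAP_RATIO_CUTOFF,
) -> tuple[float, bool]:
    """Differential bases overlapping the gene +/- 2 kb, divided by the
    unflanked gene length. Overlapping differential regions are unioned
    before counting so no base is counted twice."""
    glen = len(gene.interval)
    if glen == 0:
        raise ValueError("zero-length gene")
    lo = gene.interval.start - flank
    hi = gene.interval.end + flank
    spans = sorted(
        (max(r.interval.start, lo), min(r.interval.end, hi))
        for r in regions
        if r.interval.chrom == gene.interval.chrom
        and r.interval.start < hi
        and r.interval.end > lo
    )
    bases = 0
    cursor = None
    for s, e in spans:
        if cursor is None or s > cursor:
            bases += e - s
            cursor = e
        elif e > cursor:
            bases += e - cursor
            cursor = e
    ratio = bases / glen
    return ratio, ratio >= cutoff


def call_differential_genes(
    regions_per_comparison: dict[str, list[DifferentialRegion]],
    genes: list[GeneModel],
    flank: int = GENE_FLANK,
    cutoff: float = OVERLAP_RATIO_CUTOFF,
    exclude: set[str] | None = None,
) -> pd.DataFrame:
    """Gene-level calls: a gene passes when its overlap ratio reaches 0.09
    in at least one comparison (per-comparison max, not summed)."""
    exclude = exclude or set()
    rows = []
    for g in genes:
        detail = {}
        for comp, regions in regions_per_comparison.items():
            ratio, _ = gene_overlap_ratio(regions, g, flank=flank, cutoff=cutoff)
            detail[comp] = ratio
        best = max(detail.values()) if detail else 0.0
        rows.append(
            {
                "gene_id": g.gene_id,
                "overlap_ratio": best,
                "passes": best >= cutoff and g.gene_id not in exclude,
                **{f"ratio_{c}": v for c, v in detail.items()},
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def gene_level_log2fc(
    tracks: dict[str, CoverageTrack],
    sheet: pd.DataFrame,
    genes: list[GeneModel],
    factors: pd.Series,
    assay: str,
    flank: int = GENE_FLANK,
    reference: str = "SB",
    pseudocount: float = PSEUDOCOUNT,
    fragment_length: int = FRAGMENT_LENGTH,
) -> pd.DataFrame:
    """Factor-adjusted, replicate-averaged read counts over the gene +/- 2 kb
    per condition, as log2 fold change vs SB. All-empty genes get NA."""
    sub = sheet[sheet["assay"] == assay]
    cond_samples = {c: s["sample_id"].tolist() for c, s in sub.groupby("condition")}
    rows = {}
    for g in genes:
        chrom = g.interval.chrom
        per_cond = {}
        for cond, samples in cond_samples.items():
            vals = []
            for sid in samples:
                arr = tracks[sid].depth.get(chrom)
                if arr is None:
                    vals.append(0.0)
                    continue
                lo = max(0, g.interval.start - flank)
                hi = min(len(arr), g.interval.end + flank)
                vals.append(arr[lo:hi].sum() / fragment_length / factors[sid])
            per_cond[cond] = float(np.mean(vals))
        row = dict(per_cond)
        for cond in cond_samples:
            if cond == reference:
                continue
            if per_cond[cond] == 0 and per_cond[reference] == 0:
                row[f"log2fc_{cond}"] = np.nan
            else:
                row[f"log2fc_{cond}"] = float(
                    np.log2((per_cond[cond] + pseudocount) / (per_cond[reference] + pseudocount))
                )
        rows[g.gene_id] = row
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    out.index.name = "gene_id"
    return out
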