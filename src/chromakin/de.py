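"""Differential expression: median-of-ratios normalization, low-expression
filtering, a simplified negative-binomial Wald test per stimulated condition
versus the signal-inhibited (SB) reference, and the regulated-gene filters.

The test is deliberately NOT a DESeq clone: dispersion is a single
method-of-moments estimate pooled across groups and genes (median over
genes), with no shrinkage toward a mean-dispersion trend. The contribution
here is the filter/classification layer that consumes the test output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

LOG2FC_CUTOFF = 0.7
FDR_CUTOFF = 0.05
MIN_TOTAL_READS = 30
PSEUDOCOUNT = 0.5
REFERENCE_CONDITION = "SB"
STIMULATED = ("Activin1h", "Activin8h")
LN2 = float(np.log(2.0))


class NormalizationError(ValueError):
    pass


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style median-of-ratios size factors.

    s_j = median over genes of count_ij / geometric mean_i; genes containing
    any zero are excluded from the median.
    """
    if counts.shape[1] < 2:
        raise NormalizationError("need >= 2 samples")
    mat = counts.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if not all_nonzero.any():
        raise NormalizationError("no gene with nonzero counts in every sample")
    sub = mat[all_nonzero]
    log_geo = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = np.exp(np.log(sub) - log_geo)
    return pd.Series(np.median(ratios, axis=0), index=counts.columns, name="size_factor")


def filter_low_expression(counts: pd.DataFrame, percentile: float = 40.0) -> pd.Index:
    """Genes whose mean count across samples reaches the given percentile of
    the per-gene-mean distribution (linear-interpolation percentile)."""
    means = counts.mean(axis=1)
    cutoff = np.percentile(means.to_numpy(), percentile)
    return counts.index[means >= cutoff]


def pooled_dispersion(norm: np.ndarray, groups: list[np.ndarray]) -> float:
    """Common NB dispersion: per-gene method-of-moments residual estimates
    within each group, pooled across groups and genes.

    A per-gene two-replicate variance cannot calibrate a Wald test, so one
    common value is pooled across genes. The per-gene estimate
    (v - m) / m^2 is unbiased but heavily right-skewed at two replicates:
    its median sits far below the true dispersion and would inflate the
    type-I error, so pooling uses a lightly trimmed mean instead.
    """
    ests = []
    for idx in groups:
        sub = norm[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 0
        ests.append((v[ok] - m[ok]) / m[ok] ** 2)
    pooled = np.concatenate(ests) if ests else np.array([0.0])
    if pooled.size == 0:
        return 1e-8
    return float(max(np.mean(pooled), 1e-8))


@dataclass
class DEComparison:
    condition: str
    log2fc: pd.Series
    pvalue: pd.Series
    fdr: pd.Series
    mean_ref: pd.Series
    mean_cond: pd.Series


def nb_differential(
    counts: pd.DataFrame,
    sample_condition: pd.Series,
    condition: str,
    reference: str = REFERENCE_CONDITION,
    factors: pd.Series | None = None,
    dispersion: float | None = None,
) -> DEComparison:
    """NB Wald test of `condition` vs `reference` on normalized counts.

    Per gene: log2fc = log2((mean_cond + 0.5) / (mean_ref + 0.5)) of
    normalized means; the Wald statistic uses the NB variance m + a*m^2 with
    the pooled dispersion a. Genes all-zero in both groups get (0, 1).
    BH adjustment is applied across the genes present in `counts`.
    """
    cond_cols = sample_condition.index[sample_condition == condition]
    ref_cols = sample_condition.index[sample_condition == reference]
    if len(cond_cols) < 2 or len(ref_cols) < 2:
        raise ValueError("need >= 2 replicates per group")
    if factors is None:
        factors = size_factors(counts[list(cond_cols) + list(ref_cols)])
    norm = counts.div(factors, axis=1)
    a = counts.columns.get_indexer(cond_cols)
    b = counts.columns.get_indexer(ref_cols)
    mat = norm.to_numpy(dtype=float)
    if dispersion is None:
        dispersion = pooled_dispersion(mat, [a, b])
    mA = mat[:, a].mean(axis=1)
    mB = mat[:, b].mean(axis=1)
    lfc = np.log2((mA + PSEUDOCOUNT) / (mB + PSEUDOCOUNT))
    # delta-method variance of log(mean+pc): Var(mhat)/(n*(m+pc)^2)
    varA = (mA + dispersion * mA**2) / len(a) / (mA + PSEUDOCOUNT) ** 2
    varB = (mB + dispersion * mB**2) / len(b) / (mB + PSEUDOCOUNT) ** 2
    se_ln = np.sqrt(varA + varB)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se_ln > 0, lfc * LN2 / se_ln, 0.0)
    pval = 2.0 * stats.norm.sf(np.abs(z))
    both_zero = (counts.iloc[:, a].sum(axis=1) == 0) & (counts.iloc[:, b].sum(axis=1) == 0)
    lfc = np.where(both_zero, 0.0, lfc)
    pval = np.where(both_zero, 1.0, pval)
    fdr = bh_adjust(pval)
    idx = counts.index
    return DEComparison(
        condition=condition,
        log2fc=pd.Series(lfc, index=idx),
        pvalue=pd.Series(pval, index=idx),
        fdr=pd.Series(fdr, index=idx),
        mean_ref=pd.Series(mB, index=idx),
        mean_cond=pd.Series(mA, index=idx),
    )


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


@dataclass
class DETable:
    """Per-gene results for every condition vs the reference."""

    comparisons: dict[str, DEComparison]
    counts: pd.DataFrame
    factors: pd.Series
    retained: pd.Index = field(default=None)  # genes surviving the 40th-pct filter

    def frame(self) -> pd.DataFrame:
        cols = {}
        for cond, cmp_ in self.comparisons.items():
            cols[f"log2fc_{cond}"] = cmp_.log2fc
            cols[f"pvalue_{cond}"] = cmp_.pvalue
            cols[f"fdr_{cond}"] = cmp_.fdr
            cols[f"mean_{cond}"] = cmp_.mean_cond
        first = next(iter(self.comparisons.values()))
        cols[f"mean_{REFERENCE_CONDITION}"] = first.mean_ref
        return pd.DataFrame(cols)


def run_de(
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    conditions: tuple[str, ...] = ("Activin1h", "Activin8h", "Untreated"),
    percentile: float = 40.0,
) -> DETable:
    """Full DE stage: normalize, filter low expression, test each condition."""
    rna = sheet[sheet["assay"] == "RNA"]
    if "treatment" in rna.columns:
        rna = rna[rna["treatment"].fillna("") == ""]
    cols = rna["sample_id"].tolist()
    counts = counts[cols]
    sample_condition = pd.Series(rna["condition"].to_numpy(), index=cols)
    retained = filter_low_expression(counts, percentile)
    sub = counts.loc[retained]
    factors = size_factors(sub)
    comparisons = {
        cond: nb_differential(sub, sample_condition, cond, factors=factors)
        for cond in conditions
    }
    return DETable(comparisons=comparisons, counts=counts, factors=factors, retained=retained)


def apply_target_filters(
    table: DETable,
    fdr_cutoff: float = FDR_CUTOFF,
    lfc_cutoff: float = LOG2FC_CUTOFF,
    min_total_reads: int = MIN_TOTAL_READS,
    min_reads_mode: str = "sum",
    sample_condition: pd.Series | None = None,
) -> pd.DataFrame:
    """Regulated-gene table with reason codes.

    Keep genes with fdr < 0.05 and |log2fc| >= 0.7 in at least one
    stimulated-vs-SB comparison; drop genes with < 30 raw reads summed over
    all samples (or in every condition, with min_reads_mode='per_condition');
    drop genes whose only passing comparison is Untreated.
    """
    frame = table.frame()
    passes = {}
    for cond in table.comparisons:
        passes[cond] = (frame[f"fdr_{cond}"] < fdr_cutoff) & (
            frame[f"log2fc_{cond}"].abs() >= lfc_cutoff
        )
    pass_any = pd.DataFrame(passes).any(axis=1)
    pass_stim = pd.DataFrame({c: passes[c] for c in passes if c != "Untreated"}).any(axis=1)

    raw = table.counts.loc[frame.index]
    if min_reads_mode == "sum":
        low_reads = raw.sum(axis=1) < min_total_reads
    elif min_reads_mode == "per_condition":
        if sample_condition is None:
            raise ValueError("per_condition mode requires sample_condition")
        cond_sums = raw.T.groupby(sample_condition.loc[raw.columns]).sum().T
        low_reads = (cond_sums < min_total_reads).all(axis=1)
    else:
        raise ValueError(f"unknown min_reads_mode {min_reads_mode!r}")

    reason = pd.Series("", index=frame.index, dtype=object)
    reason[~pass_any] = "no_significant_comparison"
    reason[pass_any & ~pass_stim] = "untreated_only"
    reason[pass_any & low_reads] = "low_reads"
    keep = pass_any & pass_stim & ~low_reads
    out = frame.copy()
    out["regulated"] = keep
    out["reason"] = np.where(keep, "pass", reason)
    return out


def fpkm(counts: pd.DataFrame, exon_kb: pd.Series) -> pd.DataFrame:
    """Fragments per kilobase of exon per million mapped fragments."""
    if (exon_kb.loc[counts.index] <= 0).any():
        raise ValueError("exon_kb must be positive for every gene")
    millions = counts.sum(axis=0) / 1e6
    return counts.div(exon_kb.loc[counts.index], axis=0).div(millions, axis=1)
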