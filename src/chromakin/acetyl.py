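"""Histone-acetylation signal at binding loci: per-locus summed signal,
hierarchical clustering, the three low/high stratification schemes, and the
binding-strength comparison between classes."""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .core.io import CoverageTrack

log = logging.getLogger(__name__)

LOCUS_WINDOW = 2_500
INDUCTION_LFC_CUTOFF = 0.7
SIGNIFICANCE_ALPHA = 0.01


def locus_signal(
    tracks: dict[str, CoverageTrack],
    loci: list[tuple[str, str, int]],  # (locus_id, chrom, center)
    factors: pd.Series,
    window: int = LOCUS_WINDOW,
    reference: str = "SB",
    sample_condition: pd.Series | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Factor-adjusted read-count sum per locus (center +/- 2.5 kb) per
    sample; off-chromosome windows are clipped with a warning. When
    sample_condition is given, per-condition means and log2FC vs SB are
    appended."""
    rows = {}
    for locus_id, chrom, center in loci:
        row = {}
        for sid, tr in tracks.items():
            arr = tr.depth.get(chrom)
            if arr is None:
                row[sid] = 0.0
                continue
            lo, hi = center - window, center + window + 1
            if lo < 0 or hi > len(arr):
                log.warning("locus %s window clipped at chromosome end", locus_id)
            lo, hi = max(0, lo), min(len(arr), hi)
            row[sid] = float(arr[lo:hi].sum()) / factors[sid]
        rows[locus_id] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "locus_id"
    if sample_condition is not None:
        for cond in sample_condition.unique():
            cols = sample_condition.index[sample_condition == cond]
            frame[f"mean_{cond}"] = frame[list(cols)].mean(axis=1)
        for cond in sample_condition.unique():
            if cond == reference:
                continue
            frame[f"log2fc_{cond}"] = np.log2(
                (frame[f"mean_{cond}"] + pseudocount) / (frame[f"mean_{reference}"] + pseudocount)
            )
    return frame


def hcluster_loci(
    signal: pd.DataFrame, n_clusters: int = 2, method: str = "average"
) -> pd.Series:
    """Agglomerative clustering of loci (euclidean, average linkage).

    Flat labels are relabeled by descending cluster mean signal so that
    label 1 is always the highest-signal cluster; the result is invariant
    to input row order.
    """
    if len(signal) < 2:
        return pd.Series([1] * len(signal), index=signal.index, name="cluster")
    order = signal.index.argsort()
    sorted_signal = signal.iloc[order]
    mat = sorted_signal.to_numpy(dtype=float)
    if np.allclose(mat, mat[0]):
        return pd.Series(1, index=signal.index, name="cluster")
    z = linkage(mat, method=method, metric="euclidean")
    flat = fcluster(z, t=n_clusters, criterion="maxclust")
    means = {c: mat[flat == c].mean() for c in np.unique(flat)}
    rank = {c: i + 1 for i, c in enumerate(sorted(means, key=means.get, reverse=True))}
    labels = pd.Series([rank[c] for c in flat], index=sorted_signal.index, name="cluster")
    return labels.reindex(signal.index)


def classify_overall(k9_labels: pd.Series, k27_labels: pd.Series) -> pd.Series:
    """Low = low cluster in BOTH marks; high = high in both; otherwise
    unlabeled. Cluster 1 is high (highest mean) by hcluster_loci convention."""
    common = k9_labels.index.intersection(k27_labels.index)
    out = pd.Series("", index=common, dtype=object, name="overall")
    both_high = (k9_labels.loc[common] == 1) & (k27_labels.loc[common] == 1)
    both_low = (k9_labels.loc[common] == 2) & (k27_labels.loc[common] == 2)
    out[both_high] = "high"
    out[both_low] = "low"
    if not (both_high.any() or both_low.any()):
        log.warning("overall classification produced no labeled loci")
    return out


def classify_sb_baseline(
    k9_sb: pd.Series, k27_sb: pd.Series, n_extreme: int = 100
) -> pd.Series:
    """Per mark, rank the SB signal and take the n most and least enriched
    loci; labels are the cross-mark intersections. With fewer than 2n loci
    the selection is scaled down proportionally."""
    common = k9_sb.index.intersection(k27_sb.index)
    if len(common) < 2 * n_extreme:
        scaled = max(1, len(common) // 2)
        log.warning("only %d loci; scaling selection from %d to %d", len(common), n_extreme, scaled)
        n_extreme = scaled
    out = pd.Series("", index=common, dtype=object, name="sb_baseline")
    low, high = None, None
    for series in (k9_sb.loc[common], k27_sb.loc[common]):
        ranked = series.sort_values(kind="stable")
        lo = set(ranked.index[:n_extreme])
        hi = set(ranked.index[-n_extreme:])
        low = lo if low is None else (low & lo)
        high = hi if high is None else (high & hi)
    out[out.index.isin(low)] = "low_baseline"
    out[out.index.isin(high)] = "high_baseline"
    return out


def classify_induction_split(
    k9_lfc8h: pd.Series,
    k27_lfc8h: pd.Series,
    low_baseline_loci: pd.Index,
    cutoff: float = INDUCTION_LFC_CUTOFF,
) -> pd.Series:
    """Split low-SB-baseline loci by induction: high_increase iff the 8-hr
    log2FC reaches >= 0.7 in BOTH acetylation marks."""
    out = pd.Series("", index=low_baseline_loci, dtype=object, name="induction_split")
    both = (k9_lfc8h.loc[low_baseline_loci] >= cutoff) & (
        k27_lfc8h.loc[low_baseline_loci] >= cutoff
    )
    out[both] = "high_increase"
    out[~both] = "no_increase"
    return out


def compare_groups(
    values: pd.Series, labels: pd.Series, alpha: float = SIGNIFICANCE_ALPHA
) -> pd.DataFrame:
    """Per-class mean with t-based 95% CI, plus a Welch unpaired t-test
    between the two largest classes (significant at p < 0.01)."""
    rows = []
    groups = {}
    for lab in labels.unique():
        if lab == "":
            continue
        vals = values.loc[labels.index[labels == lab]].dropna()
        groups[lab] = vals
        if len(vals) < 2:
            log.warning("class %s has < 2 members; CI is NA", lab)
            rows.append({"label": lab, "n": len(vals), "mean": float(vals.mean()) if len(vals) else np.nan,
                         "ci_low": np.nan, "ci_high": np.nan})
            continue
        m = float(vals.mean())
        sem = stats.sem(vals)
        half = sem * stats.t.ppf(0.975, len(vals) - 1)
        rows.append({"label": lab, "n": len(vals), "mean": m, "ci_low": m - half, "ci_high": m + half})
    frame = pd.DataFrame(rows)
    big = sorted(groups, key=lambda k: len(groups[k]), reverse=True)[:2]
    if len(big) == 2 and all(len(groups[b]) >= 2 for b in big):
        t, p = stats.ttest_ind(groups[big[0]], groups[big[1]], equal_var=False)
        frame.attrs["t"] = float(t)
        frame.attrs["p"] = float(p)
        frame.attrs["significant"] = bool(p < alpha)
    else:
        frame.attrs["t"] = math.nan
        frame.attrs["p"] = math.nan
        frame.attrs["significant"] = False
    return frame


def correlate_marks(x: pd.Series, y: pd.Series, pseudocount: float = 0.5, log2: bool = True) -> float:
    """Pearson correlation (on log2 values with pseudocount by default)."""
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors of >= 3 values")
    xv, yv = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if log2:
        xv, yv = np.log2(xv + pseudocount), np.log2(yv + pseudocount)
    if np.std(xv) == 0 or np.std(yv) == 0:
        return math.nan
    return float(stats.pearsonr(xv, yv)[0])
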