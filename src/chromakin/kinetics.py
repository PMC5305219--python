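"""Rule-based kinetic classification of regulated genes and one-phase
mRNA-decay fitting.

Categories (log2 fold changes are all relative to the SB-inhibited sample):

* induced_sustained: l1h >= 0.7; l8h > l1h; luntr >= 0
* transient_induced: l1h >= 0.7; 0 <= l8h < l1h; -0.7 <= luntr <= 0.7
* delayed:           l1h <= 0.7; l8h >= 0.7; luntr > 0
* repressed:         l8h <= -0.7; luntr <= 0

Rules are applied in that order; the first match wins, otherwise the gene is
unclassified. The printed repressed threshold (l8h <= 0.7) is treated as a
sign typo — a repressed gene must clear the |log2FC| >= 0.7 filter downward;
the literal rule is available with repressed_literal_sign=True.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

CATEGORIES = ("induced_sustained", "transient_induced", "delayed", "repressed")
BASELINE_READ_CUTOFF = 30
DIRECTNESS_CUTOFF = 0.5


class FitError(RuntimeError):
    pass


def classify_kinetics(
    l1h: float, l8h: float, luntr: float, repressed_literal_sign: bool = False
) -> str:
    for v in (l1h, l8h, luntr):
        if not math.isfinite(v):
            raise ValueError(f"non-finite log2FC: {(l1h, l8h, luntr)}")
    if l1h >= 0.7 and l8h > l1h and luntr >= 0:
        return "induced_sustained"
    if l1h >= 0.7 and 0 <= l8h < l1h and -0.7 <= luntr <= 0.7:
        return "transient_induced"
    if l1h <= 0.7 and l8h >= 0.7 and luntr > 0:
        return "delayed"
    repressed_cut = 0.7 if repressed_literal_sign else -0.7
    if l8h <= repressed_cut and luntr <= 0:
        return "repressed"
    return "unclassified"


def classify_baseline(sb_reads: float) -> str:
    """'off' iff fewer than 30 reads were detected in the SB sample."""
    if sb_reads < 0:
        raise ValueError("negative read count")
    return "off" if sb_reads < BASELINE_READ_CUTOFF else "on"


def classify_directness(
    category: str,
    l8h_chx: float | None = None,
    l8h_eme: float | None = None,
    l1h_chx: float | None = None,
    l1h_eme: float | None = None,
) -> str:
    """Direct vs indirect from the protein-synthesis-inhibitor experiment.

    Indirect iff, in BOTH the cycloheximide- and emetine-treated samples:
    induced_sustained/delayed — the 8-hr log2FC does not reach > 0.5;
    repressed — it does not reach < -0.5; transient_induced — the 8-hr
    log2FC exceeds the 1-hr log2FC (loss of the transient down-turn).
    """
    if category not in CATEGORIES:
        return "not_applicable"
    if l8h_chx is None or l8h_eme is None:
        return "not_applicable"
    if category in ("induced_sustained", "delayed"):
        return "indirect" if (l8h_chx <= 0.5 and l8h_eme <= 0.5) else "direct"
    if category == "repressed":
        return "indirect" if (l8h_chx >= -0.5 and l8h_eme >= -0.5) else "direct"
    # transient_induced
    if l1h_chx is None or l1h_eme is None:
        return "not_applicable"
    return "indirect" if (l8h_chx > l1h_chx and l8h_eme > l1h_eme) else "direct"


def classify_table(
    de_frame: pd.DataFrame,
    counts: pd.DataFrame | None = None,
    sb_columns: list[str] | None = None,
    inhibitor: pd.DataFrame | None = None,
    repressed_literal_sign: bool = False,
) -> pd.DataFrame:
    """Kinetic calls for every row of a DE frame (regulated genes).

    Requires columns log2fc_Activin1h / log2fc_Activin8h / log2fc_Untreated.
    Baseline uses raw SB reads (summed over SB replicates) when counts and
    sb_columns are given. The optional inhibitor frame carries columns
    l1h_chx, l8h_chx, l1h_eme, l8h_eme indexed by gene.
    """
    rows = []
    for gid, row in de_frame.iterrows():
        cat = classify_kinetics(
            row["log2fc_Activin1h"],
            row["log2fc_Activin8h"],
            row["log2fc_Untreated"],
            repressed_literal_sign=repressed_literal_sign,
        )
        if counts is not None and sb_columns:
            baseline = classify_baseline(counts.loc[gid, sb_columns].sum())
        else:
            baseline = "on"
        if inhibitor is not None and gid in inhibitor.index:
            irow = inhibitor.loc[gid]
            directness = classify_directness(
                cat,
                l8h_chx=irow.get("l8h_chx"),
                l8h_eme=irow.get("l8h_eme"),
                l1h_chx=irow.get("l1h_chx"),
                l1h_eme=irow.get("l1h_eme"),
            )
        else:
            directness = "not_applicable"
        rows.append((gid, cat, baseline, directness))
    return pd.DataFrame(
        rows, columns=["gene_id", "category", "baseline", "directness"]
    ).set_index("gene_id")


@dataclass(frozen=True)
class DecayFit:
    y0: float
    plateau: float
    k: float  # 1/hr
    rss: float

    @property
    def half_life(self) -> float:
        return math.log(2.0) / self.k


def fit_one_phase_decay(t: np.ndarray, y: np.ndarray) -> DecayFit:
    """Least-squares fit of y = (y0 - plateau) * exp(-k t) + plateau.

    Initialized from a log-linear regression of (y - min y); k is bounded to
    (1e-6, 1e3) per hour. Raises FitError for unidentifiable (constant)
    series, non-convergence, or a boundary-stuck k.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 4 or t.size != y.size:
        raise ValueError("need >= 4 (t, y) points")
    if t[0] != 0:
        raise ValueError("first time point must be 0")
    if np.ptp(y) == 0 or np.std(y) < 1e-12 * max(1.0, abs(y[0])):
        raise FitError("constant series: decay rate unidentifiable")

    span = y - y.min() + 1e-9 * max(1.0, np.ptp(y))
    slope, intercept = np.polyfit(t, np.log(span), 1)
    k0 = float(np.clip(-slope, 1e-4, 1e2))
    p0 = (float(y[0]), float(y.min()), k0)
    lo = (-np.inf, -np.inf, 1e-6)
    hi = (np.inf, np.inf, 1e3)

    def model(tt, y0, plateau, k):
        return (y0 - plateau) * np.exp(-k * tt) + plateau

    try:
        popt, _ = curve_fit(model, t, y, p0=p0, bounds=(lo, hi), maxfev=10000)
    except RuntimeError as exc:
        raise FitError(f"decay fit did not converge: {exc}") from exc
    y0_hat, plateau_hat, k_hat = map(float, popt)
    if not (1e-6 < k_hat < 1e3) or math.isclose(k_hat, 1e-6) or math.isclose(k_hat, 1e3):
        raise FitError(f"k at bound: {k_hat}")
    rss = float(np.sum((model(t, *popt) - y) ** 2))
    return DecayFit(y0=y0_hat, plateau=plateau_hat, k=k_hat, rss=rss)
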