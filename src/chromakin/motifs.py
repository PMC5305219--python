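"""Directed IUPAC motif scanning of summit-centered sequences, positional
distributions, k-let-preserving shuffle backgrounds, background enrichment
and the 2x2 chi-square comparison."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class MotifError(ValueError):
    pass


@dataclass(frozen=True)
class MotifPattern:
    name: str
    iupac_string: str

    def __post_init__(self) -> None:
        if not self.iupac_string:
            raise MotifError("empty pattern")
        bad = set(self.iupac_string.upper()) - set(IUPAC)
        if bad:
            raise MotifError(f"invalid IUPAC letters {sorted(bad)} in {self.name!r}")


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    offset: int  # match start relative to the sequence center
    strand: str
    matched: str


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def _matches(seq: str, pattern: str, pos: int) -> bool:
    for i, p in enumerate(pattern):
        if seq[pos + i] not in IUPAC[p]:
            return False
    return True


def iupac_scan(seq: str, pattern: MotifPattern, sequence_id: str = "") -> list[MotifHit]:
    """All positions (both strands, overlapping hits included) where the
    pattern matches under IUPAC semantics. Minus-strand hits are matches of
    the reverse-complemented pattern, reported in forward coordinates.
    Offsets are match starts relative to the center base (len // 2)."""
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise MotifError(f"sequence contains non-nucleotide letters {sorted(bad)}")
    pat = pattern.iupac_string.upper()
    rc = reverse_complement(pat)
    center = len(seq) // 2
    hits = []
    for pos in range(len(seq) - len(pat) + 1):
        sub = seq[pos : pos + len(pat)]
        if _matches(seq, pat, pos):
            hits.append(MotifHit(sequence_id, pos - center, "+", sub))
        # palindromic patterns (rc == pat) are reported once, on '+'
        if rc != pat and _matches(seq, rc, pos):
            hits.append(MotifHit(sequence_id, pos - center, "-", sub))
    return hits


def positional_distribution(
    hits: list[MotifHit], binsize: int = 10, central_window: int = 50
) -> tuple[pd.DataFrame, float]:
    """Strand-collapsed histogram of hit offsets plus the central-enrichment
    score (fraction of hits within +/- 50 bp of the summit)."""
    if not hits:
        return pd.DataFrame({"bin_start": [], "count": []}), math.nan
    offsets = np.array([h.offset for h in hits])
    lo = (offsets.min() // binsize) * binsize
    hi = ((offsets.max() // binsize) + 1) * binsize
    edges = np.arange(lo, hi + binsize, binsize)
    counts, _ = np.histogram(offsets, bins=edges)
    central = float(np.mean(np.abs(offsets) <= central_window))
    return pd.DataFrame({"bin_start": edges[:-1], "count": counts}), central


# ---------------------------------------------------------------------------
# k-let-preserving shuffle (Altschul-Erickson Eulerian walk, k = 3)
# ---------------------------------------------------------------------------


def trinuc_shuffle(seq: str, rng: np.random.Generator, max_tries: int = 1000) -> str:
    """Shuffle preserving the exact trinucleotide (and dinucleotide) multiset.

    The sequence is an Eulerian path on the graph whose vertices are
    dinucleotides and whose edges are trinucleotides; a uniform-ish random
    Eulerian path with the same endpoints is drawn by reserving, for each
    non-terminal vertex, a random final out-edge forming an arborescence
    into the terminal vertex, then shuffling the remaining edges.
    """
    if len(seq) < 3:
        log.warning("sequence shorter than 3; returned unshuffled")
        return seq
    edges: dict[str, list[str]] = {}
    n = len(seq)
    for i in range(n - 2):
        edges.setdefault(seq[i : i + 2], []).append(seq[i + 1 : i + 3])
    start, end = seq[:2], seq[-2:]
    verts = list(edges)

    last: dict[str, str] = {}
    for _ in range(max_tries):
        last = {
            v: edges[v][rng.integers(len(edges[v]))][-2:] if v != end else ""
            for v in verts
        }
        if _reaches_end(last, verts, end):
            break
    else:  # pragma: no cover - astronomically unlikely
        log.warning("arborescence sampling failed; returned unshuffled")
        return seq

    ordered: dict[str, list[str]] = {}
    for v in verts:
        pool = list(edges[v])
        if v != end:
            pool.remove(last[v])
        idx = rng.permutation(len(pool))
        shuffled = [pool[i] for i in idx]
        if v != end:
            shuffled.append(last[v])
        ordered[v] = shuffled

    out = [seq[0], seq[1]]
    ptr = {v: 0 for v in verts}
    cur = start
    total = n - 2
    for _ in range(total):
        nxt = ordered[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt[-1])
        cur = nxt
    result = "".join(out)
    assert _klet_counts(result, 3) == _klet_counts(seq, 3), "shuffle broke 3-mer counts"
    return result


def _reaches_end(last: dict[str, str], verts: list[str], end: str) -> bool:
    for v in verts:
        if v == end:
            continue
        seen = {v}
        cur = v
        while cur != end:
            cur = last.get(cur, "")
            if cur == "" or cur in seen:
                return False
            seen.add(cur)
    return True


def _klet_counts(seq: str, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        counts[kmer] = counts.get(kmer, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# Enrichment against background sets
# ---------------------------------------------------------------------------


def sequence_hit_fraction(seqs: dict[str, str], pattern: MotifPattern) -> float:
    if not seqs:
        raise MotifError("empty sequence set")
    n_hit = sum(1 for sid, s in seqs.items() if iupac_scan(s, pattern, sid))
    return n_hit / len(seqs)


def background_enrichment(
    pattern: MotifPattern,
    targets: dict[str, str],
    backgrounds: dict[str, dict[str, str]],
) -> pd.DataFrame:
    """Fraction of sequences with >= 1 hit in the target set and each
    background set, with fold enrichment target/background (NA when the
    background fraction is 0)."""
    target_frac = sequence_hit_fraction(targets, pattern)
    rows = [{"set": "target", "fraction": target_frac, "fold": 1.0}]
    for name, seqs in backgrounds.items():
        frac = sequence_hit_fraction(seqs, pattern)
        fold = target_frac / frac if frac > 0 else math.nan
        rows.append({"set": name, "fraction": frac, "fold": fold})
    return pd.DataFrame(rows)


def shuffled_background(
    seqs: dict[str, str], rng: np.random.Generator
) -> dict[str, str]:
    return {f"{sid}_shuf": trinuc_shuffle(s, rng) for sid, s in seqs.items()}


def window_presence(
    seqs: dict[str, str], pattern: MotifPattern, window: int = 100
) -> pd.Series:
    """Presence of the motif within a window (default 100 bp) centered on
    the summit (= sequence center) of each summit-centered sequence."""
    half = window // 2
    out = {}
    for sid, s in seqs.items():
        hits = iupac_scan(s, pattern, sid)
        plen = len(pattern.iupac_string)
        out[sid] = any(-half <= h.offset and h.offset + plen <= half + 1 for h in hits)
    return pd.Series(out, name="present")


def chi_square_2x2(table: np.ndarray, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df = 1, no continuity correction
    by default. Warns when an expected cell is below 1."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    expected = row @ col / total
    if (expected < 1).any():
        log.warning("expected cell < 1; chi-square approximation is poor")
    diff = np.abs(obs - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff**2 / expected).sum())
    return stat, float(stats.chi2.sf(stat, df=1))


def read_patterns(path) -> list[MotifPattern]:
    """Pattern file: one `name<TAB>IUPAC` per line, '#' comments allowed."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, iupac = line.split("\t")[:2]
            out.append(MotifPattern(name, iupac))
    return out
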