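import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chromakin.core.io import CoverageTrack
from chromakin.polii import (
    DifferentialRegion,
    NormalizationError,
    call_differential_windows,
    gene_level_log2fc,
    gene_overlap_ratio,
    harmonize_sb_geomean,
    normalization_factors,
)
from chromakin.core.intervals import GenomicInterval
from .conftest import make_gene

L = 200_000


def _track(depth_value=10.0, length=L, rng=None, planted=None):
    arr = np.full(length, float(depth_value))
    if rng is not None:
        arr = rng.poisson(depth_value, size=length).astype(float)
    if planted:
        for lo, hi, mult in planted:
            arr[lo:hi] *= mult
    return CoverageTrack(depth={"chr1": arr})


class TestNormalizationFactors:
    def test_identical_samples(self, rng):
        base = rng.poisson(20, size=L).astype(float)
        tracks = {f"s{i}": CoverageTrack(depth={"chr1": base.copy()}) for i in range(3)}
        f = normalization_factors(tracks)
        np.testing.assert_allclose(f.to_numpy(), 1.0, atol=1e-9)

    def test_scaling_equivariance(self, rng):
        base = rng.poisson(20, size=L).astype(float)
        tracks = {
            "a": CoverageTrack(depth={"chr1": base.copy()}),
            "b": CoverageTrack(depth={"chr1": base * 3.0}),
        }
        f = normalization_factors(tracks)
        assert f["b"] / f["a"] == pytest.approx(3.0, rel=1e-6)

    def test_planted_enrichment_excluded(self, rng):
        # genome with genuine shared high-signal regions plus ~1% of bins
        # enriched in one sample only: the CV filter must keep factors at
        # the library-size ratio (1.0)
        base = rng.poisson(50, size=L).astype(float)
        shared = rng.choice(L // 1_000, size=60, replace=False)
        for b in shared:
            base[b * 1_000 : (b + 1) * 1_000] *= 8.0
        enriched = base.copy()
        only = [b for b in range(L // 1_000) if b not in set(shared)][:2]
        for b in only:
            enriched[b * 1_000 : (b + 1) * 1_000] *= 40.0
        tracks = {
            "a": CoverageTrack(depth={"chr1": base.copy()}),
            "b": CoverageTrack(depth={"chr1": base.copy()}),
            "c": CoverageTrack(depth={"chr1": enriched}),
        }
        f = normalization_factors(tracks)
        assert f["c"] / f["a"] == pytest.approx(1.0, abs=0.02)

    def test_too_few_bins_error(self):
        tracks = {
            "a": CoverageTrack(depth={"chr1": np.ones(5_000)}),
            "b": CoverageTrack(depth={"chr1": np.ones(5_000)}),
        }
        with pytest.raises(NormalizationError):
            normalization_factors(tracks, binsize=1_000)


class TestHarmonize:
    def test_single_comparison_identity(self):
        f = pd.Series({"sb1": 1.1, "sb2": 0.9, "t1": 1.3})
        out = harmonize_sb_geomean({"c1": f}, {"c1": ["sb1", "sb2"]})
        pd.testing.assert_series_equal(out["c1"], f)

    def test_two_comparisons(self):
        f1 = pd.Series({"sb1": 1.2, "sb2": 1.2, "t1": 2.0})
        f2 = pd.Series({"sb1": 0.8, "sb2": 0.8, "t2": 1.0})
        out = harmonize_sb_geomean({"c1": f1, "c2": f2}, {"c1": ["sb1", "sb2"], "c2": ["sb1", "sb2"]})
        g1 = stats.gmean(out["c1"][["sb1", "sb2"]])
        g2 = stats.gmean(out["c2"][["sb1", "sb2"]])
        assert g1 == pytest.approx(1.2)
        assert g2 == pytest.approx(1.2)
        # within-comparison ratios preserved exactly
        assert out["c2"]["t2"] / out["c2"]["sb1"] == pytest.approx(1.0 / 0.8)

    def test_geomean_invariant_to_1e12(self, rng):
        comps, sbs = {}, {}
        for i in range(4):
            vals = rng.uniform(0.5, 2.0, size=5)
            comps[f"c{i}"] = pd.Series(vals, index=[f"s{j}" for j in range(5)])
            sbs[f"c{i}"] = ["s0", "s1"]
        out = harmonize_sb_geomean(comps, sbs)
        ref = stats.gmean(out["c0"][sbs["c0"]])
        for c in comps:
            assert abs(stats.gmean(out[c][sbs[c]]) - ref) < 1e-12


class TestDifferentialWindows:
    factors = pd.Series({"t1": 1.0, "t2": 1.0, "r1": 1.0, "r2": 1.0})

    def test_identical_groups_no_regions(self, rng):
        base = rng.poisson(30, size=50_000).astype(float)
        treat = {s: CoverageTrack(depth={"chr1": base.copy()}) for s in ("t1", "t2")}
        ref = {s: CoverageTrack(depth={"chr1": base.copy()}) for s in ("r1", "r2")}
        regions = call_differential_windows(treat, ref, self.factors)
        assert regions == []

    def test_planted_block_recovered(self, rng):
        n = 50_000
        lo, hi = 20_000, 25_000
        treat = {}
        ref = {}
        for s in ("t1", "t2"):
            arr = rng.poisson(30, size=n).astype(float)
            arr[lo:hi] *= 3.0
            treat[s] = CoverageTrack(depth={"chr1": arr})
        for s in ("r1", "r2"):
            ref[s] = CoverageTrack(depth={"chr1": rng.poisson(30, size=n).astype(float)})
        regions = call_differential_windows(treat, ref, self.factors)
        up = [r for r in regions if r.direction == "up"]
        assert up, "no up region found"
        covered = sum(
            max(0, min(r.interval.end, hi) - max(r.interval.start, lo)) for r in up
        )
        assert covered >= 0.8 * (hi - lo)

    def test_empty_coverage(self):
        treat = {s: CoverageTrack(depth={"chr1": np.zeros(10_000)}) for s in ("t1", "t2")}
        ref = {s: CoverageTrack(depth={"chr1": np.zeros(10_000)}) for s in ("r1", "r2")}
        assert call_differential_windows(treat, ref, self.factors) == []


def _region(lo, hi, direction="up", chrom="chr1"):
    return DifferentialRegion(GenomicInterval(chrom, lo, hi), direction, 5.0, 0.001)


class TestOverlapRatio:
    def test_exact_boundary(self):
        gene = make_gene("g", "chr1", 10_000, 20_000, "+")
        ratio, passes = gene_overlap_ratio([_region(12_000, 12_900)], gene)
        assert ratio == pytest.approx(0.09)
        assert passes

    def test_no_overlap(self):
        gene = make_gene("g", "chr1", 10_000, 20_000, "+")
        ratio, passes = gene_overlap_ratio([_region(50_000, 60_000)], gene)
        assert ratio == 0.0 and not passes

    def test_flank_counts_in_numerator_only(self):
        gene = make_gene("g", "chr1", 10_000, 20_000, "+")
        # region entirely within the upstream 2-kb flank
        ratio, _ = gene_overlap_ratio([_region(8_500, 9_500)], gene)
        assert ratio == pytest.approx(1_000 / 10_000)

    def test_against_per_base_oracle(self, rng):
        gene = make_gene("g", "chr1", 50_000, 58_000, "+")
        for _ in range(200):
            regions = [
                _region(int(s), int(s) + int(rng.integers(100, 4_000)))
                for s in rng.integers(30_000, 70_000, size=int(rng.integers(0, 8)))
            ]
            mask = np.zeros(100_000, dtype=bool)
            for r in regions:
                mask[r.interval.start : r.interval.end] = True
            expected = mask[48_000:60_000].sum() / 8_000
            ratio, _ = gene_overlap_ratio(regions, gene)
            assert ratio == pytest.approx(expected)

    def test_monotone_in_region_set(self, rng):
        gene = make_gene("g", "chr1", 50_000, 58_000, "+")
        regions = []
        last = 0.0
        for _ in range(20):
            s = int(rng.integers(40_000, 64_000))
            regions.append(_region(s, s + 1_000))
            ratio, _ = gene_overlap_ratio(regions, gene)
            assert ratio >= last - 1e-12
            last = ratio


class TestGeneLevelLog2FC:
    sheet = pd.DataFrame({
        "sample_id": ["p_SB_r1", "p_SB_r2", "p_Activin1h_r1", "p_Activin1h_r2"],
        "assay": ["PolII-Ser5P"] * 4,
        "condition": ["SB", "SB", "Activin1h", "Activin1h"],
        "replicate": [1, 2, 1, 2],
    })
    factors = pd.Series(1.0, index=sheet["sample_id"])

    def test_identical_conditions(self):
        tracks = {s: _track(10.0, length=30_000) for s in self.sheet["sample_id"]}
        gene = make_gene("g", "chr1", 10_000, 12_000, "+")
        out = gene_level_log2fc(tracks, self.sheet, [gene], self.factors, "PolII-Ser5P")
        assert abs(out.loc["g", "log2fc_Activin1h"]) < 1e-6

    def test_planted_two_fold(self):
        tracks = {}
        for s in self.sheet["sample_id"]:
            mult = 2.0 if "Activin1h" in s else 1.0
            tracks[s] = _track(10.0, length=30_000, planted=[(8_000, 14_000, mult)])
        gene = make_gene("g", "chr1", 10_000, 12_000, "+")
        out = gene_level_log2fc(tracks, self.sheet, [gene], self.factors, "PolII-Ser5P")
        assert out.loc["g", "log2fc_Activin1h"] == pytest.approx(1.0, abs=0.1)

    def test_empty_region_is_na(self):
        tracks = {s: _track(0.0, length=30_000) for s in self.sheet["sample_id"]}
        gene = make_gene("g", "chr1", 10_000, 12_000, "+")
        out = gene_level_log2fc(tracks, self.sheet, [gene], self.factors, "PolII-Ser5P")
        assert np.isnan(out.loc["g", "log2fc_Activin1h"])


def test_end_to_end_polii_recovery(small_bundle, small_run):
    _, _, results = small_run
    truth = set(small_bundle.truth["polii_genes"].index)
    called = set(results["polii"].index[results["polii"]["passes"]])
    assert called == truth
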