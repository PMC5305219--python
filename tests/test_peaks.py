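import numpy as np
import pandas as pd
import pytest

from chromakin.core.intervals import GenomicInterval
from chromakin.core.io import Peak
from chromakin.peaks import (
    ConsensusPeak,
    annotate_peak,
    associate_peaks,
    build_consensus,
    filter_peaks,
    normalized_peak_counts,
    peak_density_profile,
    smad2_footprint,
)
from .conftest import make_gene


def _peak(start, end, summit=None, fold=5.0, chrom="chr1", cond="Activin1h"):
    return Peak(
        GenomicInterval(chrom, start, end),
        summit=summit if summit is not None else (start + end) // 2,
        fold_enrichment=fold, qvalue=10.0, condition=cond,
    )


class TestFilterPeaks:
    def test_fold_boundary(self):
        kept = filter_peaks([_peak(0, 100, fold=2.9), _peak(200, 300, fold=3.0)])
        assert [p.interval.start for p in kept] == [200]

    def test_repeat_overlap(self):
        repeats = [GenomicInterval("chr1", 0, 60)]
        # 60% inside the repeat -> dropped at the default 0.5 threshold
        kept = filter_peaks([_peak(0, 100)], repeats)
        assert kept == []
        # 40% inside -> kept
        kept = filter_peaks([_peak(20, 120)], [GenomicInterval("chr1", 0, 60)])
        assert len(kept) == 1

    def test_against_per_base_oracle(self, rng):
        for _ in range(100):
            peaks = [
                _peak(s, s + int(rng.integers(20, 200)))
                for s in rng.integers(0, 5000, size=int(rng.integers(1, 12)))
            ]
            repeats = [
                GenomicInterval("chr1", int(s), int(s) + int(rng.integers(20, 300)))
                for s in rng.integers(0, 5000, size=int(rng.integers(0, 8)))
            ]
            mask = np.zeros(6000, dtype=bool)
            for r in repeats:
                mask[r.start : r.end] = True
            expected = [
                p for p in peaks
                if mask[p.interval.start : p.interval.end].mean() < 0.5
            ]
            got = filter_peaks(peaks, repeats)
            assert [(p.interval.start, p.interval.end) for p in got] == [
                (p.interval.start, p.interval.end) for p in expected
            ]


class TestBuildConsensus:
    def test_chain_merge(self):
        cps = build_consensus([_peak(100, 200), _peak(150, 300), _peak(400, 500)])
        assert [(c.interval.start, c.interval.end) for c in cps] == [(100, 300), (400, 500)]
        assert len(cps[0].members) == 2

    def test_disjoint_unchanged(self):
        cps = build_consensus([_peak(0, 10), _peak(20, 30)])
        assert len(cps) == 2

    def test_avg_summit(self):
        cps = build_consensus([_peak(100, 200, summit=120), _peak(150, 300, summit=211)])
        assert cps[0].avg_summit == 166  # round(mean(120, 211))

    def test_members_overlap_merged_interval(self, rng):
        peaks = [
            _peak(int(s), int(s) + int(rng.integers(20, 150)))
            for s in rng.integers(0, 3000, size=40)
        ]
        for cp in build_consensus(peaks):
            for m in cp.members:
                assert m.interval.overlaps(cp.interval)
            assert cp.interval.contains(cp.avg_summit)


class TestAnnotatePeak:
    genes = [
        make_gene("gPlus", "chr1", 10_000, 20_000, "+", exons=[(10_000, 11_000), (19_000, 20_000)]),
        make_gene("gMinus", "chr1", 40_000, 50_000, "-"),
    ]

    def _cp(self, summit):
        return ConsensusPeak(
            interval=GenomicInterval("chr1", summit - 50, summit + 50),
            members=[_peak(summit - 50, summit + 50, summit=summit)],
        )

    def test_tss_window(self):
        assert annotate_peak(self._cp(9_700), self.genes) == "TSS"  # 300 bp upstream
        assert annotate_peak(self._cp(10_400), self.genes) == "TSS"
        # minus-strand gene: TSS at 49,999
        assert annotate_peak(self._cp(49_600), self.genes) == "TSS"

    def test_exon_vs_intron(self):
        assert annotate_peak(self._cp(10_600), self.genes) == "exonic"
        assert annotate_peak(self._cp(15_000), self.genes) == "intronic"

    def test_intergenic_strand_aware(self):
        # downstream of gPlus (+), upstream of gMinus (-): nearest decides
        assert annotate_peak(self._cp(21_000), self.genes) == "downstream_intergenic"
        assert annotate_peak(self._cp(51_500), self.genes) == "upstream_intergenic"

    def test_empty_gene_set_error(self):
        with pytest.raises(ValueError):
            annotate_peak(self._cp(100), [])

    def test_against_membership_oracle(self, rng):
        genes = []
        for i, s in enumerate(range(5_000, 95_000, 9_000)):
            strand = "+" if i % 2 == 0 else "-"
            genes.append(make_gene(f"g{i}", "chr1", s, s + 3_000, strand,
                                   exons=[(s, s + 500), (s + 2_000, s + 3_000)]))
        for _ in range(300):
            summit = int(rng.integers(600, 99_000))
            label = annotate_peak(self._cp(summit), genes)
            near_tss = any(abs(summit - g.tss) <= 500 for g in genes)
            in_exon = any(any(e.contains(summit) for e in g.exons) for g in genes)
            in_gene = any(g.interval.contains(summit) for g in genes)
            if near_tss:
                assert label == "TSS"
            elif in_exon:
                assert label == "exonic"
            elif in_gene:
                assert label == "intronic"
            else:
                assert label in ("upstream_intergenic", "downstream_intergenic")


class TestNormalizedCounts:
    def test_scaling(self):
        cp = ConsensusPeak(GenomicInterval("chr1", 100, 200), members=[_peak(100, 200)])
        positions = {"chr1": np.sort(np.concatenate([np.arange(100, 150), np.arange(500, 600)]))}
        normalized_peak_counts(positions, total_mapped=20_000_000, consensus=[cp], sample_id="s")
        assert cp.norm_counts["s"] == pytest.approx(50 * 2.0)

    def test_identity_at_40m(self):
        cp = ConsensusPeak(GenomicInterval("chr1", 0, 10), members=[_peak(0, 10)])
        normalized_peak_counts({"chr1": np.array([1, 5, 9])}, 40_000_000, [cp], "s")
        assert cp.norm_counts["s"] == 3.0

    def test_zero_total_error(self):
        cp = ConsensusPeak(GenomicInterval("chr1", 0, 10), members=[_peak(0, 10)])
        with pytest.raises(ValueError):
            normalized_peak_counts({}, 0, [cp], "s")


class TestAssociatePeaks:
    def test_nearest_and_cutoff(self):
        ga = make_gene("A", "chr1", 100_000, 110_000, "+")
        gb = make_gene("B", "chr1", 250_000, 260_000, "+")
        cp_near = ConsensusPeak(GenomicInterval("chr1", 159_950, 160_050),
                                members=[_peak(159_950, 160_050, summit=160_000)])
        associate_peaks([cp_near], [ga, gb])
        # 50 kb from A's TTS vs ~90 kb from B's TSS
        assert cp_near.gene_id == "A"
        cp_far = ConsensusPeak(GenomicInterval("chr1", 500_000, 500_100),
                               members=[_peak(500_000, 500_100, summit=500_050)])
        associate_peaks([cp_far], [ga, gb])
        assert cp_far.gene_id is None

    def test_against_all_pairs_oracle(self, rng):
        genes = [
            make_gene(f"g{i}", "chr1", int(s), int(s) + 2_000, "+")
            for i, s in enumerate(rng.integers(0, 800_000, size=12))
        ]
        from chromakin.core.intervals import nearest_gene_distance

        for _ in range(200):
            summit = int(rng.integers(0, 900_000))
            cp = ConsensusPeak(GenomicInterval("chr1", summit, summit + 1),
                               members=[_peak(summit, summit + 1, summit=summit)])
            associate_peaks([cp], genes)
            dists = {g.gene_id: nearest_gene_distance("chr1", summit, g) for g in genes}
            best = min(dists, key=lambda k: (dists[k], k))
            expected = best if dists[best] <= 100_000 else None
            assert cp.gene_id == expected


class TestFootprint:
    sheet = pd.DataFrame({
        "sample_id": ["smad2_SB_r1", "smad2_SB_r2", "smad2_Activin1h_r1", "smad2_Activin1h_r2"],
        "assay": ["SMAD2"] * 4,
        "condition": ["SB", "SB", "Activin1h", "Activin1h"],
        "replicate": [1, 2, 1, 2],
    })

    def _cp(self, gene, counts):
        cp = ConsensusPeak(GenomicInterval("chr1", 0, 100), members=[_peak(0, 100)])
        cp.gene_id = gene
        cp.norm_counts = counts
        return cp

    def test_sum_over_peaks(self):
        c1 = self._cp("g", {"smad2_SB_r1": 100, "smad2_SB_r2": 140,
                            "smad2_Activin1h_r1": 120, "smad2_Activin1h_r2": 120})
        c2 = self._cp("g", {"smad2_SB_r1": 60, "smad2_SB_r2": 100,
                            "smad2_Activin1h_r1": 80, "smad2_Activin1h_r2": 80})
        fp = smad2_footprint([c1, c2], self.sheet)
        assert fp.loc["g", "SB"] == pytest.approx(120 + 80)
        assert fp.loc["g", "Activin1h"] == pytest.approx(120 + 80)

    def test_no_peaks_gene_absent(self):
        fp = smad2_footprint([], self.sheet)
        assert len(fp) == 0
        assert "SB" in fp.columns and "log2fc_Activin1h" in fp.columns

    def test_additivity_under_split(self):
        whole = self._cp("g", {"smad2_SB_r1": 100, "smad2_SB_r2": 100,
                               "smad2_Activin1h_r1": 200, "smad2_Activin1h_r2": 200})
        half1 = self._cp("g", {"smad2_SB_r1": 60, "smad2_SB_r2": 60,
                               "smad2_Activin1h_r1": 110, "smad2_Activin1h_r2": 110})
        half2 = self._cp("g", {"smad2_SB_r1": 40, "smad2_SB_r2": 40,
                               "smad2_Activin1h_r1": 90, "smad2_Activin1h_r2": 90})
        a = smad2_footprint([whole], self.sheet)
        b = smad2_footprint([half1, half2], self.sheet)
        pd.testing.assert_frame_equal(a, b)

    def test_conservation(self, small_bundle, small_run):
        _, out, results = small_run
        fp = results["footprints"]
        cp = pd.read_csv(out / "peaks" / "consensus_peaks.tsv", sep="\t")
        assigned = cp[cp["gene_id"].notna() & (cp["gene_id"] != "")]
        for cond in ("SB", "Activin1h", "Activin8h", "Untreated"):
            cols = [c for c in cp.columns if c.startswith(f"norm_smad2_{cond}_")]
            total_assigned = assigned[cols].mean(axis=1).sum()
            # the TSV carries 6 significant digits per peak
            assert fp[cond].sum() == pytest.approx(total_assigned, rel=1e-4)


class TestDensityProfile:
    def test_coordinates(self):
        g_plus = make_gene("g", "chr1", 100_000, 150_000, "+")
        genes = {"g": g_plus}

        def cp_at(summit):
            c = ConsensusPeak(GenomicInterval("chr1", summit - 10, summit + 10),
                              members=[_peak(summit - 10, summit + 10, summit=summit)])
            c.gene_id = "g"
            return c

        # summit at TSS -> modeled coordinate 0; midpoint of 50-kb gene -> 10 kb
        prof = peak_density_profile([cp_at(100_000), cp_at(125_000)], genes)
        nonzero = prof[prof["count"] > 0]["bin_start"].tolist()
        assert nonzero == [0, 10_000]

    def test_minus_strand_orientation(self):
        g = make_gene("g", "chr1", 100_000, 150_000, "-")
        cp = ConsensusPeak(GenomicInterval("chr1", 149_990, 150_010),
                           members=[_peak(149_990, 150_010, summit=149_999)])
        cp.gene_id = "g"
        prof = peak_density_profile([cp], {"g": g})
        nonzero = prof[prof["count"] > 0]["bin_start"].tolist()
        assert nonzero == [0]  # TSS of a minus-strand gene
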