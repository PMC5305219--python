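"""Stage orchestration over a study directory (as written by the simulator
or assembled from equivalent real inputs).

Expected layout of the study directory:

    counts.tsv  samples.tsv  genes.gtf  repeats.bed  chrom_lengths.tsv
    peaks/smad2_<condition>.narrowPeak        (per-condition calls)
    peaks/smad2_<condition>_rep<r>.narrowPeak (per-replicate calls)
    reads/smad2_<condition>_r<r>.bed          (SMAD2 fragment reads)
    coverage/<sample>.bedGraph                (Pol II / acetyl / H3 tracks)
    sequences/*.fa  patterns.tsv  [inhibitor_lfc.tsv]

Each stage writes its tables under <out>/<stage>/ and returns its result so
`run_all` can chain the stages in memory.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import acetyl as acetyl_mod
from . import de as de_mod
from . import integrate as integrate_mod
from . import kinetics as kin_mod
from . import motifs as motif_mod
from . import peaks as peaks_mod
from . import polii as polii_mod
from . import profiles as prof_mod
from .core.io import (
    CONDITIONS,
    read_bed,
    read_counts,
    read_coverage,
    read_fasta,
    read_gene_models,
    read_peaks,
    read_sample_sheet,
)

log = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


def _read_chrom_lengths(study: Path) -> dict[str, int]:
    out = {}
    with open(study / "chrom_lengths.tsv") as fh:
        for line in fh:
            chrom, length = line.split("\t")
            out[chrom] = int(length)
    return out


def _mkout(outdir: Path, stage: str) -> Path:
    d = outdir / stage
    d.mkdir(parents=True, exist_ok=True)
    return d


def stage_de(study: Path, outdir: Path) -> pd.DataFrame:
    counts = read_counts(study / "counts.tsv")
    sheet = read_sample_sheet(study / "samples.tsv")
    table = de_mod.run_de(counts, sheet)
    results = de_mod.apply_target_filters(table)
    out = _mkout(outdir, "de")
    results.to_csv(out / "de_results.tsv", sep="\t", float_format=FLOAT_FMT, index_label="gene_id")
    regulated = results[results["regulated"]]
    regulated.to_csv(out / "regulated_genes.tsv", sep="\t", float_format=FLOAT_FMT, index_label="gene_id")
    table.factors.to_csv(out / "size_factors.tsv", sep="\t", float_format=FLOAT_FMT)
    return results


def stage_kinetics(study: Path, outdir: Path, de_results: pd.DataFrame | None = None) -> pd.DataFrame:
    if de_results is None:
        de_results = pd.read_csv(outdir / "de" / "de_results.tsv", sep="\t", index_col=0)
    counts = read_counts(study / "counts.tsv")
    sheet = read_sample_sheet(study / "samples.tsv")
    rna = sheet[(sheet["assay"] == "RNA") & (sheet["condition"] == "SB")]
    sb_cols = rna["sample_id"].tolist()
    inhibitor = None
    inh_path = study / "inhibitor_lfc.tsv"
    if inh_path.exists():
        inhibitor = pd.read_csv(inh_path, sep="\t", index_col=0)
    regulated = de_results[de_results["regulated"]]
    calls = kin_mod.classify_table(regulated, counts=counts, sb_columns=sb_cols, inhibitor=inhibitor)
    out = _mkout(outdir, "kinetics")
    calls.to_csv(out / "kinetic_calls.tsv", sep="\t")
    return calls


def stage_peaks(study: Path, outdir: Path, de_results: pd.DataFrame | None = None):
    if de_results is None:
        de_results = pd.read_csv(outdir / "de" / "de_results.tsv", sep="\t", index_col=0)
    genes = read_gene_models(study / "genes.gtf")
    gene_by_id = {g.gene_id: g for g in genes}
    repeats = read_bed(study / "repeats.bed")
    sheet = read_sample_sheet(study / "samples.tsv")

    all_peaks = []
    for cond in CONDITIONS:
        p = study / "peaks" / f"smad2_{cond}.narrowPeak"
        if p.exists():
            all_peaks.extend(read_peaks(p, condition=cond))
    filtered = peaks_mod.filter_peaks(all_peaks, repeats)
    consensus = peaks_mod.build_consensus(filtered)
    for cp in consensus:
        cp.annotation = peaks_mod.annotate_peak(cp, genes)

    smad = sheet[sheet["assay"] == "SMAD2"]
    for sid in smad["sample_id"]:
        reads = pd.read_csv(
            study / "reads" / f"{sid}.bed", sep="\t", header=None,
            names=["chrom", "start", "end", "name", "score", "strand"],
        )
        positions = peaks_mod.shifted_read_positions(reads)
        peaks_mod.normalized_peak_counts(positions, len(reads), consensus, sid)

    regulated_ids = de_results.index[de_results["regulated"]]
    regulated_genes = [gene_by_id[g] for g in regulated_ids if g in gene_by_id]
    peaks_mod.associate_peaks(consensus, regulated_genes)
    footprints = peaks_mod.smad2_footprint(consensus, sheet)
    density = peaks_mod.peak_density_profile(consensus, gene_by_id)

    out = _mkout(outdir, "peaks")
    frame = peaks_mod.consensus_frame(consensus)
    frame.to_csv(out / "consensus_peaks.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    with open(out / "consensus_peaks.bed", "w") as fh:
        for cp in consensus:
            iv = cp.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{cp.peak_id}\t0\t.\n")
    footprints.to_csv(out / "footprints.tsv", sep="\t", float_format=FLOAT_FMT)
    density.to_csv(out / "peak_density.tsv", sep="\t", index=False)
    return consensus, footprints


def _assay_tracks(study: Path, sheet: pd.DataFrame, assay: str, chrom_lengths):
    sub = sheet[sheet["assay"] == assay]
    return {
        sid: read_coverage(study / "coverage" / f"{sid}.bedGraph", chrom_lengths)
        for sid in sub["sample_id"]
    }


def stage_polii(study: Path, outdir: Path, assay: str = "PolII-Ser5P"):
    sheet = read_sample_sheet(study / "samples.tsv")
    chrom_lengths = _read_chrom_lengths(study)
    genes = read_gene_models(study / "genes.gtf")
    tracks = _assay_tracks(study, sheet, assay, chrom_lengths)
    factors = polii_mod.normalization_factors(tracks)

    sub = sheet[sheet["assay"] == assay]
    sb_ids = sub[sub["condition"] == "SB"]["sample_id"].tolist()
    comparisons = [c for c in CONDITIONS if c != "SB"]
    factors_per_comp = {c: factors for c in comparisons}
    sb_per_comp = {c: sb_ids for c in comparisons}
    harmonized = polii_mod.harmonize_sb_geomean(factors_per_comp, sb_per_comp)

    regions_per_comp = {}
    for comp in comparisons:
        treat_ids = sub[sub["condition"] == comp]["sample_id"].tolist()
        regions = polii_mod.call_differential_windows(
            {s: tracks[s] for s in treat_ids},
            {s: tracks[s] for s in sb_ids},
            harmonized[comp],
        )
        regions_per_comp[comp] = regions

    gene_calls = polii_mod.call_differential_genes(regions_per_comp, genes)
    lfc = polii_mod.gene_level_log2fc(tracks, sheet, genes, factors, assay)

    out = _mkout(outdir, "polii")
    factors.to_csv(out / "norm_factors.tsv", sep="\t", float_format=FLOAT_FMT)
    with open(out / "diff_regions.bed", "w") as fh:
        for comp, regions in regions_per_comp.items():
            for r in regions:
                fh.write(
                    f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t"
                    f"{comp}_{r.direction}\t{r.statistic:.3f}\t.\n"
                )
    gene_calls.to_csv(out / "polii_gene_calls.tsv", sep="\t", float_format=FLOAT_FMT)
    lfc.to_csv(out / "polii_gene_log2fc.tsv", sep="\t", float_format=FLOAT_FMT)
    return gene_calls, lfc, factors, tracks


def stage_profiles(study: Path, outdir: Path, window: int = 2_500):
    """H3 and acetylation metaprofiles around consensus-peak summits."""
    sheet = read_sample_sheet(study / "samples.tsv")
    chrom_lengths = _read_chrom_lengths(study)
    cp = pd.read_csv(outdir / "peaks" / "consensus_peaks.tsv", sep="\t")
    anchors = [(r["chrom"], int(r["avg_summit"]), "+") for _, r in cp.iterrows()]
    out = _mkout(outdir, "profiles")
    results = {}
    for assay, cond in (("H3", "Activin1h"), ("H3K9Ac", "Activin8h"), ("H3K27Ac", "Activin8h"), ("H3K9Ac", "SB"), ("H3K27Ac", "SB")):
        sub = sheet[(sheet["assay"] == assay) & (sheet["condition"] == cond)]
        tracks = [
            read_coverage(study / "coverage" / f"{sid}.bedGraph", chrom_lengths)
            for sid in sub["sample_id"]
        ]
        mp = prof_mod.metaprofile(tracks, anchors, window)
        name = f"{assay}_{cond}"
        pd.DataFrame({"position": mp.positions, "value": mp.values}).to_csv(
            out / f"metaprofile_{name}.tsv", sep="\t", index=False, float_format=FLOAT_FMT
        )
        results[name] = mp
    return results


def stage_acetyl(study: Path, outdir: Path, factors: pd.Series | None = None):
    sheet = read_sample_sheet(study / "samples.tsv")
    chrom_lengths = _read_chrom_lengths(study)
    cp = pd.read_csv(outdir / "peaks" / "consensus_peaks.tsv", sep="\t")
    loci = [(r["peak_id"], r["chrom"], int(r["avg_summit"])) for _, r in cp.iterrows()]

    signals = {}
    for mark in ("H3K9Ac", "H3K27Ac"):
        tracks = _assay_tracks(study, sheet, mark, chrom_lengths)
        f = polii_mod.normalization_factors(tracks) if factors is None else factors
        sub = sheet[sheet["assay"] == mark]
        cond = pd.Series(sub["condition"].to_numpy(), index=sub["sample_id"])
        signals[mark] = acetyl_mod.locus_signal(tracks, loci, f, sample_condition=cond)

    cond_cols = [f"mean_{c}" for c in CONDITIONS]
    k9_cl = acetyl_mod.hcluster_loci(np.log2(signals["H3K9Ac"][cond_cols] + 1))
    k27_cl = acetyl_mod.hcluster_loci(np.log2(signals["H3K27Ac"][cond_cols] + 1))
    overall = acetyl_mod.classify_overall(k9_cl, k27_cl)
    sb_base = acetyl_mod.classify_sb_baseline(signals["H3K9Ac"]["mean_SB"], signals["H3K27Ac"]["mean_SB"])
    low_in_both = sb_base.index[sb_base == "low_baseline"]
    split = acetyl_mod.classify_induction_split(
        signals["H3K9Ac"]["log2fc_Activin8h"], signals["H3K27Ac"]["log2fc_Activin8h"], low_in_both
    )

    classes = pd.DataFrame({"overall": overall, "sb_baseline": sb_base})
    classes["induction_split"] = split.reindex(classes.index).fillna("")

    smad_cols = [c for c in cp.columns if c.startswith("norm_smad2_Activin8h")]
    smad_mean = cp.set_index("peak_id")[smad_cols].mean(axis=1)
    comparison = acetyl_mod.compare_groups(smad_mean, classes["induction_split"])

    out = _mkout(outdir, "acetyl")
    for mark, sig in signals.items():
        sig.to_csv(out / f"locus_signals_{mark}.tsv", sep="\t", float_format=FLOAT_FMT)
    classes.to_csv(out / "ac_classes.tsv", sep="\t")
    comparison.to_csv(out / "class_comparison.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    return classes, comparison


def stage_motifs(study: Path, outdir: Path, seed: int = 0):
    seqs = read_fasta(study / "sequences" / "summits.fa")
    patterns = motif_mod.read_patterns(study / "patterns.tsv")
    rng = np.random.default_rng(seed)
    backgrounds = {
        "shuffled": motif_mod.shuffled_background(seqs, rng),
        "enhancer": read_fasta(study / "sequences" / "background_enhancer.fa"),
        "matched": read_fasta(study / "sequences" / "background_matched.fa"),
    }
    out = _mkout(outdir, "motifs")
    hit_rows, enr_frames = [], []
    for pat in patterns:
        hits = []
        for sid, s in seqs.items():
            hits.extend(motif_mod.iupac_scan(s, pat, sid))
        for h in hits:
            hit_rows.append({"motif": pat.name, "sequence_id": h.sequence_id,
                             "offset": h.offset, "strand": h.strand, "matched": h.matched})
        hist, central = motif_mod.positional_distribution(hits)
        hist.to_csv(out / f"positional_{pat.name}.tsv", sep="\t", index=False)
        enr = motif_mod.background_enrichment(pat, seqs, backgrounds)
        enr.insert(0, "motif", pat.name)
        enr["central_fraction"] = central
        enr_frames.append(enr)
    pd.DataFrame(hit_rows).to_csv(out / "motif_hits.tsv", sep="\t", index=False)
    pd.concat(enr_frames).to_csv(out / "enrichment.tsv", sep="\t", index=False, float_format=FLOAT_FMT)

    # FOXH1 window presence on consensus summits + chi-square vs condition
    cseqs = read_fasta(study / "sequences" / "consensus_summits.fa")
    foxh1 = next((p for p in patterns if p.name == "FOXH1"), patterns[0])
    presence = motif_mod.window_presence(cseqs, foxh1, window=100)
    presence.to_frame().to_csv(out / "foxh1_window.tsv", sep="\t", index_label="peak_id")
    cp = pd.read_csv(outdir / "peaks" / "consensus_peaks.tsv", sep="\t")
    if "conditions" in cp.columns and len(cp):
        grp1 = cp["conditions"].str.contains("Activin1h")
        pres = cp["peak_id"].map(presence).astype("boolean").fillna(False).astype(bool)
        table = np.array([
            [int((grp1 & pres).sum()), int((grp1 & ~pres).sum())],
            [int((~grp1 & pres).sum()), int((~grp1 & ~pres).sum())],
        ])
        if table.sum() > 0 and table.sum(axis=1).min() > 0:
            stat, p = motif_mod.chi_square_2x2(table)
            with open(out / "foxh1_chisq.tsv", "w") as fh:
                fh.write("chi2\tp\n")
                fh.write(f"{stat:.6g}\t{p:.6g}\n")
    return presence


def stage_integrate(study: Path, outdir: Path, de_results=None, consensus=None,
                    footprints=None, kinetic_calls=None, polii_calls=None, polii_lfc=None):
    if de_results is None:
        de_results = pd.read_csv(outdir / "de" / "de_results.tsv", sep="\t", index_col=0)
    if polii_calls is None:
        polii_calls = pd.read_csv(outdir / "polii" / "polii_gene_calls.tsv", sep="\t", index_col=0)
    if kinetic_calls is None:
        kinetic_calls = pd.read_csv(outdir / "kinetics" / "kinetic_calls.tsv", sep="\t", index_col=0)
    if footprints is None:
        footprints = pd.read_csv(outdir / "peaks" / "footprints.tsv", sep="\t", index_col=0)
    genes = {g.gene_id: g for g in read_gene_models(study / "genes.gtf")}

    rep_peaks = {}
    for rep in (1, 2):
        pks = []
        for cond in CONDITIONS:
            p = study / "peaks" / f"smad2_{cond}_rep{rep}.narrowPeak"
            if p.exists():
                pks.extend(read_peaks(p, condition=cond))
        rep_peaks[rep] = pks
    conserved = integrate_mod.replicate_conserved_peaks(rep_peaks[1], rep_peaks[2])

    de_set = set(de_results.index[de_results["regulated"]])
    polii_set = set(polii_calls.index[polii_calls["passes"]])
    hc = integrate_mod.build_high_confidence(de_set, polii_set, genes, conserved)
    master = integrate_mod.summarize(hc, kinetic_calls, footprints, polii_lfc, consensus)

    out = _mkout(outdir, "integrate")
    hc.to_csv(out / "high_confidence.tsv", sep="\t")
    master.to_csv(out / "master_table.tsv", sep="\t", float_format=FLOAT_FMT)
    return hc, master


def run_all(study: Path, outdir: Path, seed: int = 0) -> dict:
    """Full pipeline over a study directory; returns the stage results."""
    study, outdir = Path(study), Path(outdir)
    de_results = stage_de(study, outdir)
    kinetic_calls = stage_kinetics(study, outdir, de_results)
    consensus, footprints = stage_peaks(study, outdir, de_results)
    polii_calls, polii_lfc, factors, _ = stage_polii(study, outdir)
    stage_profiles(study, outdir)
    classes, comparison = stage_acetyl(study, outdir)
    stage_motifs(study, outdir, seed=seed)
    hc, master = stage_integrate(
        study, outdir, de_results, consensus, footprints, kinetic_calls, polii_calls, polii_lfc
    )
    return {
        "de": de_results,
        "kinetics": kinetic_calls,
        "consensus": consensus,
        "footprints": footprints,
        "polii": polii_calls,
        "polii_lfc": polii_lfc,
        "acetyl_classes": classes,
        "acetyl_comparison": comparison,
        "high_confidence": hc,
        "master": master,
    }
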