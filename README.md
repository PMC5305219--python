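# chromakin

Integration pipeline linking signal-induced transcription-factor (SMAD2)
chromatin binding to transcriptional kinetics, built to run end-to-end on
synthetic studies with planted ground truth.

The pipeline covers:

- **rnaseq_de** — median-of-ratios normalization, 40th-percentile
  low-expression filter, a simplified negative-binomial Wald test of each
  condition against the signal-inhibited (SB) reference, and the
  regulated-gene filters (FDR < 0.05, |log2FC| ≥ 0.7, < 30-read and
  Untreated-only exclusions).
- **kinetics** — rule-based classification into induced-sustained /
  transient-induced / delayed / repressed, baseline on/off (< 30 SB reads),
  direct/indirect from protein-synthesis-inhibitor fold changes, and
  one-phase exponential-decay half-life fitting.
- **smad2_peaks** — fold-enrichment (≥ 3.0) and repeat filtering of
  MACS-style peak calls, consensus construction by ≥ 1-nt overlap merging,
  summit-based annotation (TSS ± 500 bp > exonic > intronic > intergenic),
  read counts normalized to a 40 × 10⁶ library with +100-bp read shift,
  peak-to-gene association (nearest regulated gene within 100 kb of
  TSS/TTS), per-gene binding footprints, and the 20-kb modeled-gene peak
  density profile.
- **polii_diff** — ChIP normalization factors from high-signal/low-variance
  bins, SB geometric-mean harmonization across comparisons, windowed
  differential-occupancy calling vs SB, and gene calls by the
  differential-base overlap ratio (≥ 0.09, gene ± 2 kb).
- **profiles** — strand-aware metaprofiles around summits/TSSs with
  Savitzky–Golay smoothing, and browser-track export (100-bp extension,
  10-bp smoothing).
- **acetylation_state** — per-locus ± 2.5-kb signal sums, hierarchical
  clustering, three low/high acetylation stratifications, and
  binding-strength comparison between classes (Welch t, p < 0.01).
- **motifs** — IUPAC motif scanning on both strands, positional
  distributions relative to summits, trinucleotide-preserving
  (Eulerian-walk) shuffle backgrounds, matched/enhancer background
  enrichment, and the 100-bp-window chi-square comparison.
- **integrate** — the high-confidence gene set (RNA ∩ Pol II, plus rescues
  by replicate-conserved peaks within 100 kb) and the per-gene master table.
- **synthetic_data** — a full 4-condition × 2-replicate study generator
  (counts, peaks, coverage, sequences) with truth tables for every planted
  call; with `noise: none` the outputs are deterministic and recovered
  exactly by the pipeline.

## CLI

```sh
# simulate a study with planted truth
chromakin simulate --seed 1 --out study/

# run individual stages (outputs land under out/<stage>/)
chromakin de      --study study/ --out out/
chromakin kinetics --study study/ --out out/
chromakin peaks   --study study/ --out out/
chromakin polii   --study study/ --out out/
chromakin profile --study study/ --out out/
chromakin acetyl  --study study/ --out out/
chromakin motifs  --study study/ --out out/ --seed 1
chromakin integrate --study study/ --out out/

# or everything at once (simulates fresh when --study is omitted)
chromakin run-all --seed 1 --out out/
```

`chromakin simulate --config cfg.yaml` accepts a YAML file overriding any
`SimulationConfig` field (gene counts, chromosome lengths, noise mode,
planted effect sizes, motif embedding, …).

## Study directory layout

```
counts.tsv  samples.tsv  genes.gtf  repeats.bed  chrom_lengths.tsv
peaks/smad2_<condition>[_rep<r>].narrowPeak
reads/smad2_<condition>_r<r>.bed       # SMAD2 fragment reads
coverage/<sample>.bedGraph             # Pol II / acetylation / H3 tracks
sequences/{summits,consensus_summits,background_*}.fa
patterns.tsv  inhibitor_lfc.tsv  truth/*.tsv
```
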