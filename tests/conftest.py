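import numpy as np
import pandas as pd
import pytest

from chromakin.core.intervals import GenomicInterval, GeneModel
from chromakin.synth import SimulationConfig, simulate_study, write_bundle


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A reduced study that keeps the full planted geometry but runs fast."""
    kwargs = dict(
        n_genes=300,
        chrom_lengths={"chr1": 1_200_000, "chr2": 1_200_000},
        n_regulated=24,
        n_polii_only=2,
        n_tail_noreseque=2,
        n_low_fold_decoys=6,
        n_repeat_decoys=4,
        n_unassigned_peaks=4,
        smad2_background_reads=8_000,
        coverage_background_depth=4.0,
        n_background_matched=60,
        n_background_enhancer=40,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def small_bundle():
    return simulate_study(small_config(seed=11))


@pytest.fixture(scope="session")
def small_study_dir(small_bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("study")
    write_bundle(small_bundle, out)
    return out


@pytest.fixture(scope="session")
def small_run(small_study_dir, tmp_path_factory):
    from chromakin import pipeline

    out = tmp_path_factory.mktemp("run")
    results = pipeline.run_all(small_study_dir, out, seed=11)
    return small_study_dir, out, results


def random_intervals(rng, n, chrom="chr1", max_pos=10_000, max_len=500):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, max_pos - 1))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, min(start + length, max_pos)))
    return out


def make_gene(gene_id, chrom, start, end, strand="+", exons=None):
    iv = GenomicInterval(chrom, start, end, strand)
    exs = tuple(GenomicInterval(chrom, s, e, strand) for s, e in (exons or []))
    return GeneModel(gene_id, iv, exs)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
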