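import numpy as np
import pytest

from diffmark.genome_io import GeneModel, GenomicInterval, HotspotRecord, Peak
from diffmark.synthetic import SimConfig


def tiny_sim_config(seed: int = 0, **overrides) -> SimConfig:
    """A small but complete study the generator can pack in well under a second."""
    kwargs = dict(
        seed=seed,
        n_chromosomes=3,
        chrom_length_max=1_200_000,
        chrom_length_min=600_000,
        n_genes=40,
        n_very_large_genes=1,
        very_large_min_bp=500_000,
        very_large_max_bp=540_000,
        mean_gene_bp=6_000,
        n_hotspots=60,
        par_length_bp=100_000,
        n_consensus_peaks=150,
        n_hotspot_peaks=20,
        n_par_peaks=6,
        n_hotspot_diff=6,
        library_sizes=(100_000, 70_000, 130_000, 90_000),
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture
def tiny_cfg() -> SimConfig:
    return tiny_sim_config()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


# ---------------------------------------------------------------- random instances


def random_intervals(rng, n, chrom_names=("chr1", "chr2"), max_pos=10_000, max_len=400):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(str(rng.choice(chrom_names)), start, start + length))
    return out


def random_peaks(rng, n, **kw):
    return [Peak(iv, f"p{i}") for i, iv in enumerate(random_intervals(rng, n, **kw))]


def random_genes(rng, n, ncrna_fraction=0.3, **kw):
    genes = []
    for i, iv in enumerate(random_intervals(rng, n, max_len=2000, **kw)):
        strand = "+" if rng.random() < 0.5 else "-"
        biotype = "ncRNA" if rng.random() < ncrna_fraction else "coding"
        genes.append(GeneModel(f"g{i}", iv, strand, biotype))
    return genes


def random_hotspots(rng, n, **kw):
    return [
        HotspotRecord(iv, int(rng.integers(0, 500)))
        for iv in random_intervals(rng, n, **kw)
    ]


# ---------------------------------------------------------------- brute-force oracles


def brute_overlap(items, query, min_overlap=1):
    """O(n) all-pairs scan; independent of the interval-tree implementation."""
    hits = []
    for item in items:
        iv = item if isinstance(item, GenomicInterval) else item.interval
        if iv.chrom != query.chrom:
            continue
        if min(iv.end, query.end) - max(iv.start, query.start) >= min_overlap:
            hits.append(item)
    return hits


def bitmap_union(intervals, chrom_len=20_000):
    """Per-base boolean masks per chromosome; the covered-base oracle."""
    masks = {}
    for iv in intervals:
        m = masks.setdefault(iv.chrom, np.zeros(chrom_len, dtype=bool))
        m[iv.start : iv.end] = True
    return masks
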