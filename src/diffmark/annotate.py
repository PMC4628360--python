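"""Genomic classification of peaks: genic/intergenic, TSS proximity, ncRNA
overlap, and per-chromosome distribution.

A peak is *genic* when it overlaps any gene body extended by ``genic_flank``
on both sides (default 1 kb); *at a TSS* when it overlaps the symmetric
window ``[tss - w, tss + w)``.  ncRNA overlap uses the bare gene body, no
flank.  Categories are non-exclusive counters: a peak may be genic, at a TSS
and on an ncRNA at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genome_io import GeneModel, GenomicInterval, IntervalIndex, Peak

__all__ = [
    "AnnotationConfig",
    "AnnotationSummary",
    "classify_genic",
    "tss_fraction",
    "ncrna_overlap",
    "chromosome_distribution",
]


@dataclass
class AnnotationConfig:
    genic_flank: int = 1000
    tss_window: int = 1000

    def __post_init__(self) -> None:
        if self.genic_flank < 0 or self.tss_window < 0:
            raise ValueError("flank and window must be >= 0")


@dataclass
class AnnotationSummary:
    n_genic: int = 0
    n_intergenic: int = 0
    n_tss: int = 0
    n_ncrna: int = 0
    per_chromosome: dict[str, tuple[int, float]] = field(default_factory=dict)


def _flanked(gene: GeneModel, flank: int) -> GenomicInterval:
    return GenomicInterval(
        gene.interval.chrom, max(0, gene.interval.start - flank), gene.interval.end + flank
    )


def classify_genic(
    peaks: Sequence[Peak], genes: Sequence[GeneModel], cfg: AnnotationConfig | None = None
) -> tuple[dict[str, str], AnnotationSummary]:
    """Label each peak genic/intergenic against flank-extended gene bodies."""
    cfg = cfg or AnnotationConfig()
    index = IntervalIndex(_flanked(g, cfg.genic_flank) for g in genes)
    labels: dict[str, str] = {}
    summary = AnnotationSummary()
    for p in peaks:
        genic = bool(index.query(p.interval))
        labels[p.peak_id] = "genic" if genic else "intergenic"
        if genic:
            summary.n_genic += 1
        else:
            summary.n_intergenic += 1
    assert summary.n_genic + summary.n_intergenic == len(peaks)
    return labels, summary


def tss_windows(genes: Sequence[GeneModel], window: int) -> list[GenomicInterval]:
    return [
        GenomicInterval(g.interval.chrom, max(0, g.tss - window), g.tss + window)
        for g in genes
    ]


def tss_fraction(
    peaks: Sequence[Peak], genes: Sequence[GeneModel], cfg: AnnotationConfig | None = None
) -> float:
    """Fraction of peaks overlapping any symmetric TSS window."""
    if not peaks:
        return 0.0
    cfg = cfg or AnnotationConfig()
    index = IntervalIndex(tss_windows(genes, cfg.tss_window))
    n_hit = sum(bool(index.query(p.interval)) for p in peaks)
    return n_hit / len(peaks)


def ncrna_overlap(
    peaks: Sequence[Peak], genes: Sequence[GeneModel]
) -> list[dict]:
    """Peaks overlapping ncRNA gene bodies (no flank), with the nearest coding
    gene on each side of the peak midpoint.

    Returns rows: peak_id, ncrna_id, upstream/downstream coding gene ids and
    signed distances (bp from peak midpoint to the nearer gene edge; negative
    means the gene lies left of the midpoint).
    """
    nc = [g for g in genes if g.biotype == "ncRNA"]
    if not nc:
        return []
    nc_index = IntervalIndex(nc)
    coding_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        if g.biotype == "coding":
            coding_by_chrom.setdefault(g.interval.chrom, []).append(g)
    for lst in coding_by_chrom.values():
        lst.sort(key=lambda g: g.interval.start)

    rows: list[dict] = []
    for p in peaks:
        hits = nc_index.query(p.interval)
        if not hits:
            continue
        mid = (p.interval.start + p.interval.end) // 2
        left = right = None
        left_d = right_d = None
        for g in coding_by_chrom.get(p.interval.chrom, []):
            if g.interval.end <= mid:
                d = g.interval.end - 1 - mid  # negative
                if left_d is None or d > left_d:
                    left, left_d = g, d
            elif g.interval.start > mid:
                d = g.interval.start - mid
                if right_d is None or d < right_d:
                    right, right_d = g, d
            else:  # gene spans the midpoint: nearest on both sides
                left, left_d = g, 0
                right, right_d = g, 0
        for h in sorted(hits, key=lambda g: g.gene_id):
            rows.append(
                {
                    "peak_id": p.peak_id,
                    "ncrna_id": h.gene_id,
                    "upstream_gene": left.gene_id if left else None,
                    "upstream_distance": left_d,
                    "downstream_gene": right.gene_id if right else None,
                    "downstream_distance": right_d,
                }
            )
    return rows


def chromosome_distribution(
    peaks: Sequence[Peak], chrom_sizes: Mapping[str, int]
) -> tuple[dict[str, tuple[int, float]], float]:
    """Per-chromosome peak counts and percents, plus the Pearson correlation
    between count and chromosome length across all chromosomes in the map."""
    counts = {chrom: 0 for chrom in chrom_sizes}
    for p in peaks:
        if p.interval.chrom not in counts:
            raise ValueError(f"peak on unknown chromosome {p.interval.chrom!r}")
        counts[p.interval.chrom] += 1
    total = max(1, len(peaks))
    table = {c: (n, 100.0 * n / total) for c, n in counts.items()}
    lengths = np.array([chrom_sizes[c] for c in counts], dtype=float)
    n_arr = np.array([counts[c] for c in counts], dtype=float)
    if len(counts) < 2 or n_arr.std() == 0 or lengths.std() == 0:
        corr = float("nan")
    else:
        corr = float(np.corrcoef(n_arr, lengths)[0, 1])
    return table, corr
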