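"""Interval-based genomic I/O and the overlap kernel.

All coordinates are BED-style 0-based half-open ``[start, end)``; intervals
touching at a single coordinate do not overlap.  Chromosome names are compared
as exact strings (no ``chr`` prefix normalisation).  Strand is used only to
place a gene's TSS; peak overlap is unstranded, as histone marks carry no
strand information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "Peak",
    "GeneModel",
    "HotspotRecord",
    "IntervalIndex",
    "read_bed",
    "write_bed",
    "read_gene_table",
    "read_hotspot_bed",
    "write_hotspot_bed",
    "overlap_query",
    "merge_intervals",
    "read_fasta",
    "write_fasta",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A located genomic span, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end}) on {self.chrom}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of shared bases; 0 for different chromosomes or touching ends."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class Peak:
    """A called enrichment peak; the unit of all overlap logic.

    ``summit`` is an offset from ``interval.start`` (narrowPeak convention);
    ``None`` when unknown (narrowPeak column 10 value of -1).
    """

    interval: GenomicInterval
    peak_id: str
    summit: Optional[int] = None
    signal: float = 0.0

    def __post_init__(self) -> None:
        if self.summit is not None and not (0 <= self.summit < len(self.interval)):
            raise ValueError(
                f"summit {self.summit} outside peak of length {len(self.interval)}"
            )
        if self.signal < 0:
            raise ValueError(f"signal must be non-negative, got {self.signal}")


@dataclass
class GeneModel:
    """A gene span with strand-derived TSS and coarse biotype."""

    gene_id: str
    interval: GenomicInterval
    strand: str
    biotype: str = "coding"
    tss: int = field(init=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.biotype not in ("coding", "ncRNA"):
            raise ValueError(f"unknown biotype {self.biotype!r}")
        self.tss = self.interval.start if self.strand == "+" else self.interval.end - 1


@dataclass
class HotspotRecord:
    """A meiotic DSB hotspot with its DMC1 SSDS tag count."""

    interval: GenomicInterval
    dmc1_tags: int

    def __post_init__(self) -> None:
        if self.dmc1_tags < 0:
            raise ValueError("dmc1_tags must be non-negative")


def _interval_of(item) -> GenomicInterval:
    if isinstance(item, GenomicInterval):
        return item
    if isinstance(item, tuple):  # (interval, payload) pairs
        return item[0]
    return item.interval


class IntervalIndex:
    """Per-chromosome interval tree over objects carrying a ``GenomicInterval``."""

    def __init__(self, items: Iterable = ()) -> None:
        self._trees: dict[str, IntervalTree] = {}
        for item in items:
            self.add(item)

    def add(self, item) -> None:
        iv = _interval_of(item)
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, item)

    def query(self, query: GenomicInterval, min_overlap: int = 1) -> list:
        """Members sharing >= ``min_overlap`` bases with ``query``, input order not guaranteed."""
        if min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        tree = self._trees.get(query.chrom)
        if tree is None:
            return []
        hits = []
        for node in tree.overlap(query.start, query.end):
            if min(node.end, query.end) - max(node.begin, query.start) >= min_overlap:
                hits.append(node.data)
        return hits


def overlap_query(index, query: GenomicInterval, min_overlap: int = 1) -> list:
    """Members of ``index`` overlapping ``query`` by at least ``min_overlap`` bases.

    ``index`` may be an :class:`IntervalIndex` or any iterable of objects with
    intervals (an index is built on the fly).
    """
    if not isinstance(index, IntervalIndex):
        index = IntervalIndex(index)
    return index.query(query, min_overlap=min_overlap)


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or bookended-overlapping intervals into a sorted disjoint set.

    Half-open semantics: ``[100,200)`` and ``[200,300)`` share no base and stay
    separate.  The union of covered bases is conserved.
    """
    out: list[GenomicInterval] = []
    for iv in sorted(intervals):
        if out and out[-1].chrom == iv.chrom and iv.start < out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


_BED_DIALECT_COLS = {"bed3": 3, "bed6": 6, "narrowPeak": 10}


def read_bed(path, dialect: str = "bed6") -> list[Peak]:
    """Read a BED3/BED6/narrowPeak file into peaks, preserving input order.

    narrowPeak: column 7 is the signal value, column 10 the summit offset
    (-1 means no summit).  Peak ids default to ``peak_<n>`` when the name
    column is absent or ``.``.
    """
    if dialect not in _BED_DIALECT_COLS:
        raise ValueError(f"unknown BED dialect {dialect!r}")
    need = _BED_DIALECT_COLS[dialect]
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < need:
                raise ValueError(
                    f"{path}:{lineno}: expected >= {need} columns for {dialect}, "
                    f"got {len(fields)}"
                )
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed coordinates") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start ({start}, {end})")
            name = fields[3] if need >= 6 and fields[3] != "." else f"peak_{lineno}"
            signal = 0.0
            summit = None
            if dialect == "narrowPeak":
                signal = float(fields[6])
                sm = int(fields[9])
                summit = sm if sm >= 0 else None
            elif dialect == "bed6":
                try:
                    signal = float(fields[4])
                except ValueError:
                    signal = 0.0
            peaks.append(
                Peak(GenomicInterval(chrom, start, end), name, summit=summit, signal=signal)
            )
    return peaks


def write_bed(peaks: Sequence[Peak], path, dialect: str = "bed6") -> None:
    """Write peaks in input order; round-trips losslessly through :func:`read_bed`."""
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            if dialect == "bed3":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            elif dialect == "bed6":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.peak_id}\t{p.signal:g}\t.\n")
            elif dialect == "narrowPeak":
                summit = -1 if p.summit is None else p.summit
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.peak_id}\t0\t.\t"
                    f"{p.signal:g}\t-1\t-1\t{summit}\n"
                )
            else:
                raise ValueError(f"unknown BED dialect {dialect!r}")


def read_gene_table(path) -> list[GeneModel]:
    """Read a 6-column TSV: gene_id, chrom, start, end, strand, biotype."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] == "gene_id":
                continue
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
            gene_id, chrom, start, end, strand, biotype = fields[:6]
            genes.append(
                GeneModel(gene_id, GenomicInterval(chrom, int(start), int(end)), strand, biotype)
            )
    return genes


def write_gene_table(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\tstrand\tbiotype\n")
        for g in genes:
            iv = g.interval
            fh.write(f"{g.gene_id}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{g.strand}\t{g.biotype}\n")


def read_hotspot_bed(path) -> list[HotspotRecord]:
    """Read a BED4 hotspot map; column 4 is the DMC1 tag count."""
    records: list[HotspotRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: hotspot BED4 needs 4 columns")
            records.append(
                HotspotRecord(
                    GenomicInterval(fields[0], int(fields[1]), int(fields[2])),
                    int(float(fields[3])),
                )
            )
    return records


def write_hotspot_bed(records: Sequence[HotspotRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            iv = r.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.dmc1_tags}\n")


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into ``{name: uppercased sequence}``.

    Record names are the first whitespace-delimited token of the header.
    Duplicate names are an error.
    """
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks).upper()
                name = line[1:].split()[0]
                if name in seqs:
                    raise ValueError(f"duplicate FASTA record {name!r}")
                chunks = []
            elif line:
                if name is None:
                    raise ValueError("sequence data before first FASTA header")
                chunks.append(line)
    if name is not None:
        if name in seqs:
            raise ValueError(f"duplicate FASTA record {name!r}")
        seqs[name] = "".join(chunks).upper()
    return seqs


def write_fasta(seqs: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
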