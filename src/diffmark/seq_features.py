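"""Sequence-composition features: AT content, maximal AT stretches, CpG counts.

An *AT stretch* is a maximal run of consecutive A/T bases of at least
``min_len`` bases; any non-A/T character (including N) breaks a run.  There
is no community-standard stretch length, so ``min_len`` is a required,
reported parameter (default 8).  Lowercase (soft-masked) bases are uppercased
before counting; masking is not used as a filter.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

from .genome_io import GeneModel

__all__ = [
    "SequenceFeatureRow",
    "at_content",
    "count_at_stretches",
    "count_cpg",
    "gene_feature_table",
]

_AT_RUN = re.compile(r"[AT]+")


@dataclass
class SequenceFeatureRow:
    region_id: str
    length_bp: int
    at_fraction: float
    n_at_stretches: int
    n_cpg: int


def at_content(seq: str) -> float:
    """(A+T) / (A+C+G+T); ambiguous bases (N) excluded from the denominator."""
    seq = seq.upper()
    at = seq.count("A") + seq.count("T")
    acgt = at + seq.count("C") + seq.count("G")
    if acgt == 0:
        raise ValueError("sequence has no unambiguous bases")
    return at / acgt


def count_at_stretches(seq: str, min_len: int = 8) -> int:
    """Number of maximal A/T runs of length >= ``min_len``."""
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    return sum(1 for m in _AT_RUN.finditer(seq.upper()) if m.end() - m.start() >= min_len)


def count_cpg(seq: str) -> int:
    """Occurrences of the CG dinucleotide (5'->3'; GC does not count)."""
    return seq.upper().count("CG")


def gene_feature_table(
    genes: Sequence[GeneModel], fasta: Mapping[str, str], min_len: int = 8
) -> list[SequenceFeatureRow]:
    """One composition row per gene, extracted from the genome sequences."""
    rows: list[SequenceFeatureRow] = []
    for g in genes:
        iv = g.interval
        seq = fasta.get(iv.chrom)
        if seq is None:
            raise ValueError(f"gene {g.gene_id}: chromosome {iv.chrom!r} not in FASTA")
        if iv.end > len(seq):
            raise ValueError(
                f"gene {g.gene_id} extends to {iv.end} beyond {iv.chrom} length {len(seq)}"
            )
        sub = seq[iv.start : iv.end]
        rows.append(
            SequenceFeatureRow(
                region_id=g.gene_id,
                length_bp=len(sub),
                at_fraction=at_content(sub),
                n_at_stretches=count_at_stretches(sub, min_len=min_len),
                n_cpg=count_cpg(sub),
            )
        )
    return rows
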