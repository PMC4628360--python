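"""Microarray-style differential expression and ChIP/expression integration.

Expression input is a gene x sample matrix of log2 intensities.  Differential
genes are called with the moderated t-test at a linear fold-change cutoff and
a *raw* p-value cutoff (arrays of this design are conventionally thresholded
on unadjusted p).  Integration links each differential gene to the H3K4me3
peaks overlapping its TSS window and reports the ChIP-side fold change, or
"ND" (not detected) when no peak lies near the TSS.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .genome_io import GeneModel, GenomicInterval, IntervalIndex
from .stats_core import (
    ModerationParams,
    NormalizedMatrix,
    TestResult,
    estimate_moderation,
    moderated_t_test,
)

log = logging.getLogger(__name__)

__all__ = ["ExpressionMatrix", "IntegrationRecord", "de_genes", "shortlist", "integrate_with_peaks"]


@dataclass
class ExpressionMatrix:
    """Gene x sample log2 intensity matrix with condition labels."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    condition: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        nf, ns = self.values.shape
        if nf != len(self.gene_ids) or ns != len(self.sample_ids):
            raise ValueError("values shape inconsistent with id lists")
        if len(self.condition) != ns:
            raise ValueError("condition labels inconsistent with sample count")


@dataclass
class IntegrationRecord:
    """One differential gene joined to the ChIP signal at its TSS."""

    gene_id: str
    fc_expression: float  # linear
    fc_chip: Optional[float]  # linear; None renders as "ND"
    tss_peak_ids: list[str]

    @property
    def nd(self) -> bool:
        return self.fc_chip is None


def de_genes(
    em: ExpressionMatrix,
    fc_cut: float = 1.5,
    p_cut: float = 0.05,
    moderation: ModerationParams | None = None,
) -> list[TestResult]:
    """Moderated t per gene; called iff linear |FC| > fc_cut and raw p < p_cut."""
    nm = NormalizedMatrix(
        list(em.gene_ids), list(em.sample_ids), em.values, list(em.condition),
        pseudocount=1.0, target=math.nan,
    )
    if moderation is None:
        cond = np.asarray(em.condition)
        ctrl = em.values[:, cond == "control"]
        trt = em.values[:, cond == "treated"]
        n1, n2 = ctrl.shape[1], trt.shape[1]
        d_g = n1 + n2 - 2
        s2 = (ctrl.var(axis=1, ddof=1) * (n1 - 1) + trt.var(axis=1, ddof=1) * (n2 - 1)) / d_g
        moderation = estimate_moderation(s2, d_g)
    results = moderated_t_test(nm, moderation)
    for r in results:
        called = (2.0 ** abs(r.log_fc)) > fc_cut and r.p_value < p_cut
        r.direction = ("up" if r.log_fc > 0 else "down") if called else "ns"
    return results


def shortlist(results: Sequence[TestResult], fc_cut: float = 2.0) -> list[str]:
    """Gene ids among the called genes with linear |FC| >= fc_cut (inclusive)."""
    return [
        r.feature_id
        for r in results
        if r.direction != "ns" and (2.0 ** abs(r.log_fc)) >= fc_cut
    ]


def integrate_with_peaks(
    de: Sequence[TestResult],
    peak_signal: Mapping[str, tuple[GenomicInterval, float, float]],
    genes: Sequence[GeneModel],
    tss_window: int = 1000,
) -> list[IntegrationRecord]:
    """Join differential genes to mean normalised ChIP signal at their TSS.

    ``peak_signal`` maps peak_id -> (interval, mean control signal, mean
    treated signal) on the linear normalised scale.  For each called gene the
    ChIP fold change is the ratio of mean treated to mean control signal over
    all peaks overlapping ``[tss - w, tss + w)``; genes with no nearby peak
    get ``fc_chip = None`` ("ND").  Every called gene yields exactly one
    record; unresolvable gene ids are skipped with a warning.
    """
    gene_map = {g.gene_id: g for g in genes}
    index = IntervalIndex()
    for pid, (iv, mc, mt) in peak_signal.items():
        index.add((iv, (pid, mc, mt)))
    records: list[IntegrationRecord] = []
    for r in de:
        if r.direction == "ns":
            continue
        g = gene_map.get(r.feature_id)
        if g is None:
            log.warning("gene %r not in annotation; skipped from integration", r.feature_id)
            continue
        win = GenomicInterval(
            g.interval.chrom, max(0, g.tss - tss_window), g.tss + tss_window
        )
        hits = index.query(win)
        if not hits:
            records.append(IntegrationRecord(g.gene_id, 2.0 ** r.log_fc, None, []))
            continue
        pids = [pid for _, (pid, _, _) in hits]
        mean_c = float(np.mean([mc for _, (_, mc, _) in hits]))
        mean_t = float(np.mean([mt for _, (_, _, mt) in hits]))
        fc_chip = (mean_t / mean_c) if mean_c > 0 else None
        records.append(
            IntegrationRecord(g.gene_id, 2.0 ** r.log_fc, fc_chip, sorted(pids))
        )
    return records
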