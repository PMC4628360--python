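"""Association of differential peaks with meiotic DSB hotspots and
region-level signal comparison (e.g. the pseudoautosomal region, PAR).

Hotspot intensity is the DMC1 SSDS tag count per hotspot, compared on the
natural-log scale; zero-tag hotspots are excluded from log-scale medians
(with a logged count) since log(0) is undefined.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .annotate import AnnotationConfig, classify_genic
from .genome_io import GeneModel, GenomicInterval, HotspotRecord, IntervalIndex, Peak
from .stats_core import ranksum_compare

log = logging.getLogger(__name__)

__all__ = [
    "HotspotAssociation",
    "RegionSignal",
    "associate_hotspots",
    "intensity_compare",
    "gene_hotspot_summary",
    "region_signal",
]


@dataclass
class HotspotAssociation:
    """Differential peaks overlapping DSB hotspots, with gene membership."""

    associated: list[tuple[str, list[int]]]  # (peak_id, indices into the hotspot list)
    n_associated_peaks: int
    n_within_genes: int


@dataclass
class RegionSignal:
    """Condition-wise mean normalised signal over a fixed region."""

    region: GenomicInterval
    mean_control: float
    mean_treated: float
    ratio: Optional[float]  # treated / control; None when undefined

    @property
    def defined(self) -> bool:
        return self.ratio is not None


def associate_hotspots(
    diff_peaks: Sequence[Peak],
    hotspots: Sequence[HotspotRecord],
    genes: Sequence[GeneModel] = (),
    min_overlap: int = 1,
    cfg: AnnotationConfig | None = None,
) -> HotspotAssociation:
    """A differential peak is hotspot-associated iff it overlaps >= ``min_overlap``
    bp of at least one hotspot.  Gene membership of associated peaks follows the
    flanked genic rule."""
    index = IntervalIndex()
    for i, h in enumerate(hotspots):
        index.add((h.interval, i))

    # tuple items: first element carries the interval
    assoc: list[tuple[str, list[int]]] = []
    assoc_peaks: list[Peak] = []
    for p in diff_peaks:
        hits = index.query(p.interval, min_overlap=min_overlap)
        if hits:
            assoc.append((p.peak_id, sorted(i for _, i in hits)))
            assoc_peaks.append(p)
    n_within = 0
    if genes and assoc_peaks:
        labels, _ = classify_genic(assoc_peaks, genes, cfg)
        n_within = sum(v == "genic" for v in labels.values())
    return HotspotAssociation(assoc, len(assoc), n_within)


def intensity_compare(
    assoc: HotspotAssociation, hotspots: Sequence[HotspotRecord]
) -> tuple[float, float, float]:
    """Median log(#tags) of hotspots linked to differential peaks vs all
    hotspots, with a rank-sum p-value.  Natural log; zero-tag hotspots dropped."""
    if assoc.n_associated_peaks == 0:
        raise ValueError("no hotspot-associated peaks; nothing to compare")
    assoc_idx = sorted({i for _, idx in assoc.associated for i in idx})
    all_tags = np.array([h.dmc1_tags for h in hotspots], dtype=float)
    assoc_tags = all_tags[assoc_idx]
    n_zero = int((all_tags == 0).sum())
    if n_zero:
        log.info("excluding %d zero-tag hotspots from log-intensity medians", n_zero)
    assoc_logs = np.log(assoc_tags[assoc_tags > 0])
    all_logs = np.log(all_tags[all_tags > 0])
    if assoc_logs.size == 0:
        raise ValueError("all associated hotspots have zero tags")
    med_a, med_all, p = ranksum_compare(assoc_logs, all_logs)
    return med_a, med_all, p


def gene_hotspot_summary(
    genes: Sequence[GeneModel], hotspots: Sequence[HotspotRecord], min_overlap: int = 1
) -> list[dict]:
    """Per-gene DSB summary: gene id, length in Mb (2 decimals), number of
    hotspots overlapping the gene body, and the highest DMC1 tag count among
    them.  Hotspots straddling a gene edge count (1-bp overlap rule)."""
    index = IntervalIndex()
    for i, h in enumerate(hotspots):
        index.add((h.interval, i))
    rows = []
    for g in genes:
        hits = index.query(g.interval, min_overlap=min_overlap)
        tags = [hotspots[i].dmc1_tags for _, i in hits]
        rows.append(
            {
                "gene_id": g.gene_id,
                "length_mb": round(len(g.interval) / 1e6, 2),
                "n_dsb": len(tags),
                "highest_dsb_signal": max(tags) if tags else 0,
            }
        )
    return rows


def region_signal(
    region_counts: Sequence[float],
    region: GenomicInterval,
    library_sizes: Sequence[float],
    condition: Sequence[str],
    target: float | None = None,
) -> RegionSignal:
    """Condition-wise mean of scale-normalised tag counts inside ``region``.

    ``region_counts`` is the per-sample tag count within the region.  The
    ratio treated/control is None (flagged undefined) when the control mean
    is zero, never infinity.
    """
    counts = np.asarray(region_counts, dtype=float)
    libs = np.asarray(library_sizes, dtype=float)
    if counts.shape != libs.shape or len(condition) != counts.size:
        raise ValueError("region_counts, library_sizes and condition must align")
    if np.any(libs <= 0):
        raise ValueError("library sizes must be positive")
    if target is None:
        target = float(libs.mean())
    scaled = counts * (target / libs)
    cond = np.asarray(condition)
    mean_c = float(scaled[cond == "control"].mean())
    mean_t = float(scaled[cond == "treated"].mean())
    ratio = (mean_t / mean_c) if mean_c > 0 else None
    if ratio is None:
        log.warning("control signal in %s is zero; ratio undefined", region)
    return RegionSignal(region, mean_c, mean_t, ratio)
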