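"""The multi-step differential-peak procedure.

Fixed stage order: per-condition replicate reproducibility -> consensus
construction -> per-peak tag quantification -> scale normalisation + log2
transform -> quantile filter on mean expression -> moderated t-test with
fold-change and FDR thresholds.  The quantile threshold is computed only over
reproducible (consensus) peaks, never over the raw peak calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .genome_io import GenomicInterval, IntervalIndex, Peak, merge_intervals
from .stats_core import (
    CountMatrix,
    ModerationParams,
    NormalizedMatrix,
    TestResult,
    bh_fdr,
    estimate_moderation,
    log_transform,
    moderated_t_test,
    scale_normalize,
)

__all__ = [
    "ReplicatePeakSets",
    "ConsensusPeak",
    "DifferentialPeakSet",
    "reproducible_peaks",
    "build_consensus",
    "quantify",
    "quantile_filter",
    "call_differential",
    "run_differential_pipeline",
]


@dataclass
class ReplicatePeakSets:
    """Per-sample peak calls with condition labels and library sizes.

    Exactly two conditions, each with at least two biological replicates.
    """

    peak_sets: list[list[Peak]]
    condition: list[str]  # per sample, {control, treated}
    library_sizes: list[float]
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.peak_sets)
        if len(self.condition) != n or len(self.library_sizes) != n:
            raise ValueError("per-sample metadata inconsistent")
        if not self.sample_ids:
            self.sample_ids = [f"{c}_{i}" for i, c in enumerate(self.condition)]
        for lab in ("control", "treated"):
            if sum(c == lab for c in self.condition) < 2:
                raise ValueError(f"condition {lab!r} needs >= 2 replicates")

    def replicates(self, label: str) -> list[list[Peak]]:
        return [ps for ps, c in zip(self.peak_sets, self.condition) if c == label]


@dataclass
class ConsensusPeak:
    """A replicate-supported interval; the unit of differential testing."""

    interval: GenomicInterval
    peak_id: str
    source: str  # control-reproducible | treated-reproducible | both


@dataclass
class DifferentialPeakSet:
    """Called differential peaks joined to their test results and thresholds."""

    results: list[TestResult]
    peaks: dict[str, ConsensusPeak]
    fc_cut: float
    fdr_cut: float
    quantile_cut: float

    @property
    def called(self) -> list[TestResult]:
        return [r for r in self.results if r.direction != "ns"]

    @property
    def n_up(self) -> int:
        return sum(r.direction == "up" for r in self.results)

    @property
    def n_down(self) -> int:
        return sum(r.direction == "down" for r in self.results)


def reproducible_peaks(
    peaks_rep1: Sequence[Peak], peaks_rep2: Sequence[Peak], min_overlap: int = 1
) -> list[Peak]:
    """Rep1 peaks supported by >= ``min_overlap`` bp overlap with some rep2 peak.

    Each kept peak is extended to the union span of itself and all its rep2
    matches, so no reproducible signal is clipped.  Order follows rep1.
    """
    index = IntervalIndex(peaks_rep2)
    kept: list[Peak] = []
    for p in peaks_rep1:
        hits = index.query(p.interval, min_overlap=min_overlap)
        if not hits:
            continue
        start = min([p.interval.start] + [h.interval.start for h in hits])
        end = max([p.interval.end] + [h.interval.end for h in hits])
        kept.append(
            Peak(
                GenomicInterval(p.interval.chrom, start, end),
                p.peak_id,
                summit=None,
                signal=p.signal,
            )
        )
    return kept


def build_consensus(sets: ReplicatePeakSets, min_overlap: int = 1) -> list[ConsensusPeak]:
    """Merge condition-wise reproducible peaks into a labelled consensus set.

    Ids are assigned in chromosome order (``cons_00001`` ...).  ``source``
    records whether the merged interval drew support from control replicates,
    treated replicates, or both.
    """
    per_condition: dict[str, list[GenomicInterval]] = {}
    for label in ("control", "treated"):
        reps = sets.replicates(label)
        repro: list[Peak] = reps[0]
        for other in reps[1:]:
            repro = reproducible_peaks(repro, other, min_overlap=min_overlap)
        per_condition[label] = merge_intervals([p.interval for p in repro])

    merged = merge_intervals(per_condition["control"] + per_condition["treated"])
    ctrl_idx = IntervalIndex(per_condition["control"])
    trt_idx = IntervalIndex(per_condition["treated"])
    out: list[ConsensusPeak] = []
    width = max(5, len(str(len(merged))))
    for i, iv in enumerate(merged, start=1):
        from_ctrl = bool(ctrl_idx.query(iv))
        from_trt = bool(trt_idx.query(iv))
        source = (
            "both"
            if from_ctrl and from_trt
            else "control-reproducible" if from_ctrl else "treated-reproducible"
        )
        out.append(ConsensusPeak(iv, f"cons_{i:0{width}d}", source))
    return out


def quantify(
    consensus: Sequence[ConsensusPeak],
    tag_positions: Sequence[Sequence[GenomicInterval]] | None,
    condition: Sequence[str],
    sample_ids: Sequence[str] | None = None,
    counts: np.ndarray | None = None,
    library_sizes: Sequence[float] | None = None,
) -> CountMatrix:
    """Count per-sample tags falling inside each consensus interval.

    Either ``tag_positions`` (per sample: a list of single-base tag intervals
    or a ``{chrom: positions array}`` mapping; library size = total tags,
    including tags outside every peak) or precomputed ``counts`` with explicit
    ``library_sizes`` must be supplied.
    """
    feature_ids = [c.peak_id for c in consensus]
    if sample_ids is None:
        sample_ids = [f"{c}_{i}" for i, c in enumerate(condition)]
    if counts is not None:
        if library_sizes is None:
            raise ValueError("library_sizes required with precomputed counts")
        return CountMatrix(feature_ids, list(sample_ids), np.asarray(counts),
                           np.asarray(library_sizes, dtype=float), list(condition))
    if tag_positions is None:
        raise ValueError("either tag_positions or counts must be provided")

    # sorted start arrays per chromosome for O(log n) membership
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    order: dict[str, np.ndarray] = {}
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for j, c in enumerate(consensus):
        by_chrom.setdefault(c.interval.chrom, []).append((c.interval.start, c.interval.end, j))
    for chrom, rows in by_chrom.items():
        rows.sort()
        starts[chrom] = np.array([r[0] for r in rows])
        ends[chrom] = np.array([r[1] for r in rows])
        order[chrom] = np.array([r[2] for r in rows])

    mat = np.zeros((len(consensus), len(condition)), dtype=int)
    libs = np.zeros(len(condition), dtype=float)
    for s, tags in enumerate(tag_positions):
        if isinstance(tags, dict):
            by_pos = {c: np.asarray(p) for c, p in tags.items()}
        else:
            by_pos = {}
            for tag in tags:
                by_pos.setdefault(tag.chrom, []).append(tag.start)
            by_pos = {c: np.asarray(p) for c, p in by_pos.items()}
        libs[s] = sum(p.size for p in by_pos.values())
        for chrom, pos in by_pos.items():
            if chrom not in starts or pos.size == 0:
                continue  # tags on chromosomes without peaks count toward depth only
            k = np.searchsorted(starts[chrom], pos, side="right") - 1
            ok = (k >= 0) & (pos < ends[chrom][np.clip(k, 0, None)])
            idx = order[chrom][k[ok]]
            np.add.at(mat[:, s], idx, 1)
    return CountMatrix(feature_ids, list(sample_ids), mat, libs, list(condition))


def quantile_filter(nm: NormalizedMatrix, q: float = 0.05) -> list[str]:
    """Retain features whose mean normalised value across all samples is
    strictly above the nearest-rank ``q`` quantile of those means."""
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if len(nm.feature_ids) < 2:
        raise ValueError("quantile filter needs >= 2 features")
    means = nm.values.mean(axis=1)
    ordered = np.sort(means)
    rank = max(1, math.ceil(q * means.size))  # nearest-rank (type-1) quantile
    threshold = ordered[rank - 1]
    retained = [fid for fid, m in zip(nm.feature_ids, means) if m > threshold]
    if not retained:
        raise ValueError(
            "quantile filter removed every feature (tied means); lower q or inspect the data"
        )
    return retained


def call_differential(
    nm: NormalizedMatrix,
    retained: Sequence[str],
    fc_cut: float = 1.5,
    fdr_cut: float = 0.05,
    moderation: Optional[ModerationParams] = None,
) -> list[TestResult]:
    """Moderated t + BH over the retained features; call iff the linear fold
    change exceeds ``fc_cut`` (as ``2**|log_fc| > fc_cut``) and ``q < fdr_cut``."""
    missing = set(retained) - set(nm.feature_ids)
    if missing:
        raise ValueError(f"retained ids not in matrix: {sorted(missing)[:5]}")
    sub = nm.subset(retained)
    if moderation is None:
        cond = np.asarray(sub.condition)
        ctrl = sub.values[:, cond == "control"]
        trt = sub.values[:, cond == "treated"]
        n1, n2 = ctrl.shape[1], trt.shape[1]
        d_g = n1 + n2 - 2
        s2 = (ctrl.var(axis=1, ddof=1) * (n1 - 1) + trt.var(axis=1, ddof=1) * (n2 - 1)) / d_g
        moderation = estimate_moderation(s2, d_g)
    results = moderated_t_test(sub, moderation)
    qs = bh_fdr([r.p_value for r in results])
    for r, q in zip(results, qs):
        r.q_value = float(q)
        called = (2.0 ** abs(r.log_fc)) > fc_cut and q < fdr_cut
        r.direction = ("up" if r.log_fc > 0 else "down") if called else "ns"
    return results


def run_differential_pipeline(
    sets: ReplicatePeakSets,
    tag_positions=None,
    counts: np.ndarray | None = None,
    min_overlap: int = 1,
    quantile_cut: float = 0.05,
    fc_cut: float = 1.5,
    fdr_cut: float = 0.05,
    pseudocount: float = 1.0,
) -> tuple[DifferentialPeakSet, CountMatrix, NormalizedMatrix]:
    """Full procedure from replicate peak calls to the differential peak set."""
    consensus = build_consensus(sets, min_overlap=min_overlap)
    cm = quantify(
        consensus,
        tag_positions,
        sets.condition,
        sample_ids=sets.sample_ids,
        counts=counts,
        library_sizes=sets.library_sizes if counts is not None else None,
    )
    scaled, target = scale_normalize(cm)
    nm = log_transform(scaled, cm, pseudocount=pseudocount, target=target)
    retained = quantile_filter(nm, q=quantile_cut)
    results = call_differential(nm, retained, fc_cut=fc_cut, fdr_cut=fdr_cut)
    dps = DifferentialPeakSet(
        results, {c.peak_id: c for c in consensus}, fc_cut, fdr_cut, quantile_cut
    )
    return dps, cm, nm
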