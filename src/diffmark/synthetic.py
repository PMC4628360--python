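"""Synthetic study generator with ground truth.

Emulates the design of a two-condition (control vs treated), two-replicate
H3K4me3 ChIP-seq study with a matched 3 vs 3 expression array:

* a small genome of a few chromosomes of decreasing length, the last one
  carrying a PAR-like region with a planted CpG island;
* non-overlapping gene models (coding + ncRNA) including a handful of very
  large (>= 0.5 Mb) AT-rich genes;
* DSB hotspots whose count per chromosome is proportional to chromosome
  length and whose DMC1 tag intensities are log-normal (heavy-tailed);
* base peaks over TSSs, strong hotspots, the PAR-like region and background,
  observed per replicate through dropout and boundary jitter;
* negative-binomial per-peak tag counts with library-size imbalance, a small
  asymmetric differential fraction (up >> down) at a fixed linear effect
  size, hotspot-linked differential peaks biased toward the strongest
  hotspots, and condition-specific signal loss in the PAR-like region;
* Gaussian log2 expression intensities with differential genes, a configured
  fraction of which are linked to a same-sign differential TSS peak.

All randomness flows from ``SimConfig.seed`` through one generator, so every
output is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .diff_peaks import ReplicatePeakSets
from .diff_expr import ExpressionMatrix
from .genome_io import GeneModel, GenomicInterval, HotspotRecord, Peak
from .stats_core import CountMatrix

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "Genome",
    "SimulatedStudy",
    "generate_genome",
    "generate_peak_replicates",
    "generate_counts",
    "generate_expression",
    "simulate_study",
    "nb_counts",
]


@dataclass
class SimConfig:
    """The study conditions the generator reproduces.

    The default scenario: 2 x 2 ChIP design over 2000
    consensus peaks with 5 % differential at linear fold change 3 and a
    97:3 up:down ratio, NB dispersion 0.05, mean depth 50 tags per peak,
    imbalanced library sizes, and a PAR-like region losing half its signal
    in the treated condition.
    """

    seed: int = 0
    # genome
    n_chromosomes: int = 6
    chrom_length_max: int = 6_000_000
    chrom_length_min: int = 2_000_000
    n_genes: int = 400
    n_very_large_genes: int = 5
    very_large_min_bp: int = 500_000
    very_large_max_bp: int = 1_100_000
    mean_gene_bp: int = 20_000
    ncrna_fraction: float = 0.15
    n_hotspots: int = 500
    hotspot_width_bp: int = 1500
    hotspot_log_mu: float = 4.0  # log-normal parameters of DMC1 tag counts
    hotspot_log_sigma: float = 1.2
    par_length_bp: int = 400_000
    par_cpg_count: int = 127
    background_at: float = 0.50
    large_gene_at: float = 0.62
    n_planted_at_stretches: int = 10
    at_stretch_min_len: int = 8
    make_sequences: bool = True
    # peaks
    n_consensus_peaks: int = 2000
    tss_peak_prob: float = 0.7
    n_hotspot_peaks: int = 90
    n_par_peaks: int = 8
    peak_width_bp: int = 900
    dropout: float = 0.1
    jitter_bp: int = 30
    # counts
    differential_fraction: float = 0.05
    up_fraction: float = 0.97
    effect_size: float = 3.0  # linear fold change of injected peaks
    n_hotspot_diff: int = 40
    nb_dispersion: float = 0.05
    mean_depth: float = 50.0
    library_sizes: tuple[float, ...] = (1_000_000, 700_000, 1_300_000, 900_000)
    condition: tuple[str, ...] = ("control", "control", "treated", "treated")
    par_ratio: float = 0.5  # treated/control signal in the PAR-like region
    background_tag_fraction: float = 0.2
    # expression
    n_expr_samples_per_condition: int = 3
    de_fraction: float = 0.05
    de_effect_size: float = 2.0  # linear
    de_up_fraction: float = 0.6
    expr_noise_sd: float = 0.25
    expr_baseline_mean: float = 7.0
    expr_baseline_sd: float = 1.0
    link_probability: float = 0.8

    def __post_init__(self) -> None:
        for name in ("ncrna_fraction", "dropout", "differential_fraction",
                     "up_fraction", "de_fraction", "link_probability",
                     "background_tag_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if len(self.library_sizes) != len(self.condition):
            raise ValueError("library_sizes and condition must align")


@dataclass
class SyntheticTruth:
    """Ground-truth labels emitted by the generator."""

    differential_log_fc: dict[str, float] = field(default_factory=dict)
    up_ids: list[str] = field(default_factory=list)
    down_ids: list[str] = field(default_factory=list)
    par_peak_ids: list[str] = field(default_factory=list)
    par_ratio: float = 1.0
    hotspot_linked_peaks: dict[str, int] = field(default_factory=dict)  # peak -> hotspot index
    de_log_fc: dict[str, float] = field(default_factory=dict)
    linked_gene_peak: dict[str, str] = field(default_factory=dict)
    planted_at_stretches: dict[str, int] = field(default_factory=dict)  # gene -> min count
    planted_cpg: Optional[tuple[str, int, int, int]] = None  # chrom, start, end, count


@dataclass
class Genome:
    chrom_sizes: dict[str, int]
    genes: list[GeneModel]
    hotspots: list[HotspotRecord]
    par_region: GenomicInterval
    sequences: dict[str, str]


@dataclass
class SimulatedStudy:
    cfg: SimConfig
    genome: Genome
    base_peaks: list[Peak]
    origins: dict[str, tuple]  # peak_id -> ("tss", gene_id) | ("hotspot", idx) | ("par",) | ("background",)
    replicate_sets: ReplicatePeakSets
    counts: CountMatrix
    tags: list[dict[str, np.ndarray]]  # per sample: chrom -> sorted tag positions
    expression: ExpressionMatrix
    truth: SyntheticTruth


# ---------------------------------------------------------------- genome


def _random_seq(rng: np.random.Generator, n: int, at: float) -> np.ndarray:
    p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n, p=p)


def _place_nonoverlapping(
    rng: np.random.Generator, chrom_len: int, lengths: list[int], margin: int
) -> list[int]:
    """Start positions for ``lengths`` laid left-to-right with random gaps."""
    total = sum(lengths) + margin * (len(lengths) + 1)
    free = chrom_len - total
    if free < 0:
        raise ValueError(
            f"cannot pack {len(lengths)} features of {sum(lengths)} bp into {chrom_len} bp"
        )
    gaps = rng.dirichlet(np.ones(len(lengths) + 1)) * free
    starts = []
    pos = 0
    for L, gap in zip(lengths, gaps):
        pos += int(gap) + margin
        starts.append(pos)
        pos += L
    return starts


def generate_genome(cfg: SimConfig, rng: np.random.Generator | None = None) -> Genome:
    """Chromosomes, gene models, hotspot map, PAR-like region and sequences."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n = cfg.n_chromosomes
    lengths = np.linspace(cfg.chrom_length_max, cfg.chrom_length_min, n).astype(int)
    names = [f"chr{i + 1}" for i in range(n - 1)] + ["chrX"]
    chrom_sizes = dict(zip(names, lengths.tolist()))

    # PAR-like region at the distal end of chrX
    x_len = chrom_sizes["chrX"]
    par = GenomicInterval("chrX", x_len - cfg.par_length_bp, x_len)

    # allocate ordinary genes to chromosomes proportionally to length
    total_len = int(lengths.sum())
    n_ordinary = cfg.n_genes - cfg.n_very_large_genes
    per_chrom = np.maximum(1, np.round(n_ordinary * lengths / total_len)).astype(int)
    n_large_per_chrom = np.zeros(n, dtype=int)
    for i in range(cfg.n_very_large_genes):
        n_large_per_chrom[i % max(1, n - 1)] += 1  # large genes on autosomes

    genes: list[GeneModel] = []
    large_gene_ids: list[str] = []
    gid = 0
    for ci, (chrom, clen) in enumerate(chrom_sizes.items()):
        glens = []
        kinds = []
        for _ in range(int(n_large_per_chrom[ci])):
            glens.append(int(rng.integers(cfg.very_large_min_bp, cfg.very_large_max_bp)))
            kinds.append("large")
        for _ in range(int(per_chrom[ci])):
            L = int(rng.exponential(cfg.mean_gene_bp)) + 2000
            glens.append(min(L, 150_000))
            kinds.append("ordinary")
        order = rng.permutation(len(glens))
        glens = [glens[i] for i in order]
        kinds = [kinds[i] for i in order]
        avail = clen - (cfg.par_length_bp if chrom == "chrX" else 0)
        starts = _place_nonoverlapping(rng, avail, glens, margin=3000)
        for start, L, kind in zip(starts, glens, kinds):
            gid += 1
            name = f"gene_{gid:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            biotype = "ncRNA" if (kind == "ordinary" and rng.random() < cfg.ncrna_fraction) else "coding"
            genes.append(GeneModel(name, GenomicInterval(chrom, start, start + L), strand, biotype))
            if kind == "large":
                large_gene_ids.append(name)

    # hotspots: count per chromosome proportional to length, log-normal tags
    hotspots: list[HotspotRecord] = []
    per_chrom_hs = np.maximum(1, np.round(cfg.n_hotspots * lengths / total_len)).astype(int)
    for chrom, clen, k in zip(names, lengths, per_chrom_hs):
        starts = np.sort(rng.integers(0, clen - cfg.hotspot_width_bp, size=int(k)))
        tags = np.maximum(
            1, np.round(rng.lognormal(cfg.hotspot_log_mu, cfg.hotspot_log_sigma, size=int(k)))
        ).astype(int)
        for s, t in zip(starts, tags):
            hotspots.append(
                HotspotRecord(GenomicInterval(chrom, int(s), int(s) + cfg.hotspot_width_bp), int(t))
            )

    sequences: dict[str, str] = {}
    truth_at: dict[str, int] = {}
    cpg_island = None
    if cfg.make_sequences:
        large = {g.gene_id: g for g in genes if g.gene_id in large_gene_ids}
        for chrom, clen in chrom_sizes.items():
            arr = _random_seq(rng, clen, cfg.background_at)
            for g in large.values():
                if g.interval.chrom != chrom:
                    continue
                s, e = g.interval.start, g.interval.end
                arr[s:e] = _random_seq(rng, e - s, cfg.large_gene_at)
                # plant fixed-length AT stretches flanked by G/C so they never merge
                run = cfg.at_stretch_min_len + 4
                span = (e - s) // (cfg.n_planted_at_stretches + 1)
                for j in range(cfg.n_planted_at_stretches):
                    pos = s + (j + 1) * span
                    block = b"G" + b"AT" * (run // 2) + b"C"
                    arr[pos : pos + len(block)] = np.frombuffer(block, dtype="S1")
                truth_at[g.gene_id] = cfg.n_planted_at_stretches
            if chrom == "chrX":
                # CpG island in the middle of the PAR-like region, exactly
                # par_cpg_count CG dinucleotides separated by A spacers
                island = b"A".join(b"CG" for _ in range(cfg.par_cpg_count))
                mid = par.start + (len(par) - len(island)) // 2
                arr[mid : mid + len(island)] = np.frombuffer(island, dtype="S1")
                cpg_island = ("chrX", mid, mid + len(island), cfg.par_cpg_count)
            sequences[chrom] = arr.tobytes().decode("ascii")

    genome = Genome(chrom_sizes, genes, hotspots, par, sequences)
    genome._truth_at = truth_at  # type: ignore[attr-defined]
    genome._cpg_island = cpg_island  # type: ignore[attr-defined]
    return genome


# ---------------------------------------------------------------- peaks


def generate_peak_replicates(
    cfg: SimConfig, genome: Genome, rng: np.random.Generator | None = None
) -> tuple[list[Peak], dict[str, tuple], ReplicatePeakSets]:
    """Base peaks over TSSs, strong hotspots, the PAR and background, then
    per-replicate observation with dropout and boundary jitter.

    Returns ``(base_peaks, origins, replicate_sets)``; base peaks are mutually
    non-overlapping (separated by at least twice the jitter) so consensus
    intervals map one-to-one onto base peaks.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    margin = 2 * cfg.jitter_bp + 10
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.chrom_sizes}

    def try_place(chrom: str, start: int, end: int) -> bool:
        clen = genome.chrom_sizes[chrom]
        if start < cfg.jitter_bp + 1 or end > clen - cfg.jitter_bp - 1:
            return False
        for s, e in occupied[chrom]:
            if start - margin < e and s < end + margin:
                return False
        occupied[chrom].append((start, end))
        return True

    base: list[Peak] = []
    origins: dict[str, tuple] = {}

    par = genome.par_region

    def add_peak(chrom: str, center: int, origin: tuple) -> bool:
        w = max(200, int(rng.normal(cfg.peak_width_bp, cfg.peak_width_bp / 6)))
        start, end = center - w // 2, center + w // 2
        if not try_place(chrom, start, end):
            return False
        # any peak inside the PAR-like region carries the region-wide signal loss
        if chrom == par.chrom and start < par.end and par.start < end:
            origin = ("par",)
        pid = f"base_{len(base) + 1:05d}"
        base.append(Peak(GenomicInterval(chrom, start, end), pid))
        origins[pid] = origin
        return True

    # TSS peaks
    for g in genome.genes:
        if rng.random() < cfg.tss_peak_prob:
            add_peak(g.interval.chrom, g.tss, ("tss", g.gene_id))

    # peaks on hotspots, sampled with probability proportional to DMC1 tags
    tags = np.array([h.dmc1_tags for h in genome.hotspots], dtype=float)
    probs = tags / tags.sum()
    chosen = rng.choice(len(tags), size=min(cfg.n_hotspot_peaks, len(tags)),
                        replace=False, p=probs)
    for idx in chosen:
        h = genome.hotspots[int(idx)]
        c = (h.interval.start + h.interval.end) // 2
        add_peak(h.interval.chrom, c, ("hotspot", int(idx)))

    # PAR-like peaks
    for _ in range(cfg.n_par_peaks):
        for _attempt in range(50):
            c = int(rng.integers(par.start + cfg.peak_width_bp, par.end - cfg.peak_width_bp))
            if add_peak(par.chrom, c, ("par",)):
                break

    # background fill
    chroms = list(genome.chrom_sizes)
    lengths = np.array([genome.chrom_sizes[c] for c in chroms], dtype=float)
    cprob = lengths / lengths.sum()
    guard = 0
    while len(base) < cfg.n_consensus_peaks and guard < 50 * cfg.n_consensus_peaks:
        guard += 1
        chrom = chroms[int(rng.choice(len(chroms), p=cprob))]
        c = int(rng.integers(cfg.peak_width_bp, genome.chrom_sizes[chrom] - cfg.peak_width_bp))
        add_peak(chrom, c, ("background",))
    if len(base) < cfg.n_consensus_peaks:
        raise ValueError("could not place the requested number of base peaks")

    # replicate observation: independent dropout + boundary jitter
    peak_sets: list[list[Peak]] = []
    for _s in range(len(cfg.condition)):
        reps: list[Peak] = []
        for p in base:
            if rng.random() < cfg.dropout:
                continue
            j1 = int(rng.integers(-cfg.jitter_bp, cfg.jitter_bp + 1))
            j2 = int(rng.integers(-cfg.jitter_bp, cfg.jitter_bp + 1))
            start = max(0, p.interval.start + j1)
            end = max(start + 1, p.interval.end + j2)
            reps.append(Peak(GenomicInterval(p.interval.chrom, start, end), p.peak_id))
        peak_sets.append(reps)

    sets = ReplicatePeakSets(
        peak_sets,
        list(cfg.condition),
        list(cfg.library_sizes),
        sample_ids=[f"{c}_{i + 1}" for i, c in enumerate(cfg.condition)],
    )
    return base, origins, sets


# ---------------------------------------------------------------- counts


def nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative-binomial draws with Var = m + dispersion * m^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if dispersion < 1e-12:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def assign_differential(
    cfg: SimConfig,
    peak_ids: list[str],
    origins: dict[str, tuple] | None,
    hotspots: list[HotspotRecord] | None,
    rng: np.random.Generator,
) -> SyntheticTruth:
    """Sample the differential subset: up:down per ``up_fraction``; a block of
    the differential peaks drawn from hotspot-linked peaks weighted by DMC1
    intensity (all 'up', mirroring elevation at strong hotspots); PAR peaks
    carry the region-wide treated/control ratio."""
    truth = SyntheticTruth(par_ratio=cfg.par_ratio)
    lfc = math.log2(cfg.effect_size)
    n_diff = int(round(cfg.differential_fraction * len(peak_ids)))

    hotspot_peaks: list[str] = []
    par_peaks: list[str] = []
    if origins:
        for pid in peak_ids:
            o = origins.get(pid, ("background",))
            if o[0] == "hotspot":
                hotspot_peaks.append(pid)
                truth.hotspot_linked_peaks[pid] = int(o[1])
            elif o[0] == "par":
                par_peaks.append(pid)

    chosen: list[str] = []
    hotspot_chosen: set[str] = set()
    if hotspot_peaks and hotspots is not None and cfg.n_hotspot_diff > 0:
        w = np.array(
            [hotspots[truth.hotspot_linked_peaks[p]].dmc1_tags for p in hotspot_peaks],
            dtype=float,
        )
        k = min(cfg.n_hotspot_diff, len(hotspot_peaks), n_diff)
        idx = rng.choice(len(hotspot_peaks), size=k, replace=False, p=w / w.sum())
        hotspot_chosen = {hotspot_peaks[i] for i in idx}
        chosen.extend(sorted(hotspot_chosen))
    pool = [p for p in peak_ids if p not in hotspot_chosen and p not in set(par_peaks)]
    n_rest = max(0, n_diff - len(chosen))
    rest = rng.choice(len(pool), size=min(n_rest, len(pool)), replace=False)
    chosen.extend(pool[i] for i in rest)

    for pid in chosen:
        if pid in hotspot_chosen:
            up = True  # elevated marks at hotspots
        else:
            up = rng.random() < cfg.up_fraction
        truth.differential_log_fc[pid] = lfc if up else -lfc
        (truth.up_ids if up else truth.down_ids).append(pid)
    for pid in par_peaks:
        truth.par_peak_ids.append(pid)
        truth.differential_log_fc[pid] = math.log2(cfg.par_ratio)
    return truth


def generate_counts(
    cfg: SimConfig,
    peak_ids: list[str],
    rng: np.random.Generator | None = None,
    origins: dict[str, tuple] | None = None,
    hotspots: list[HotspotRecord] | None = None,
    truth: SyntheticTruth | None = None,
    sample_ids: list[str] | None = None,
) -> tuple[CountMatrix, SyntheticTruth]:
    """NB tag counts per (peak, sample) under the configured effect structure.

    Expected count for peak g in sample s is
    ``depth_g * (library_s / mean library) * 2**(log_fc_g * 1[s treated])``
    with per-peak baseline depths log-normal around ``mean_depth`` and NB
    noise at ``nb_dispersion``.  Library sizes are the configured totals.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)
    if truth is None:
        truth = assign_differential(cfg, peak_ids, origins, hotspots, rng)
    libs = np.asarray(cfg.library_sizes, dtype=float)
    size_factors = libs / libs.mean()
    treated = np.array([c == "treated" for c in cfg.condition])

    depth = cfg.mean_depth * rng.lognormal(-0.125, 0.5, size=len(peak_ids))
    lfc = np.array([truth.differential_log_fc.get(p, 0.0) for p in peak_ids])
    mean = depth[:, None] * size_factors[None, :] * np.power(
        2.0, lfc[:, None] * treated[None, :]
    )
    counts = nb_counts(rng, mean, cfg.nb_dispersion)
    if sample_ids is None:
        sample_ids = [f"{c}_{i + 1}" for i, c in enumerate(cfg.condition)]
    cm = CountMatrix(list(peak_ids), sample_ids, counts, libs, list(cfg.condition))
    return cm, truth


def generate_tags(
    cfg: SimConfig,
    counts: CountMatrix,
    peaks: list[Peak],
    genome: Genome,
    rng: np.random.Generator | None = None,
) -> list[dict[str, np.ndarray]]:
    """Per-sample tag positions: counts[g, s] tags uniform within peak g plus
    genome-wide background tags (a configured fraction of in-peak tags)."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 3)
    by_id = {p.peak_id: p for p in peaks}
    out: list[dict[str, np.ndarray]] = []
    chroms = list(genome.chrom_sizes)
    lengths = np.array([genome.chrom_sizes[c] for c in chroms], dtype=float)
    cprob = lengths / lengths.sum()
    for s in range(len(counts.sample_ids)):
        positions: dict[str, list[np.ndarray]] = {c: [] for c in chroms}
        for g, pid in enumerate(counts.feature_ids):
            k = int(counts.counts[g, s])
            if k == 0:
                continue
            iv = by_id[pid].interval
            positions[iv.chrom].append(rng.integers(iv.start, iv.end, size=k))
        n_in = int(counts.counts[:, s].sum())
        n_bg = int(round(cfg.background_tag_fraction * n_in))
        bg_per_chrom = rng.multinomial(n_bg, cprob)
        for c, k in zip(chroms, bg_per_chrom):
            if k:
                positions[c].append(rng.integers(0, genome.chrom_sizes[c], size=int(k)))
        out.append(
            {
                c: np.sort(np.concatenate(v)) if v else np.array([], dtype=int)
                for c, v in positions.items()
            }
        )
    return out


# ---------------------------------------------------------------- expression


def generate_expression(
    cfg: SimConfig,
    genome: Genome,
    truth: SyntheticTruth,
    origins: dict[str, tuple] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Gaussian log2 intensities; DE genes injected, a configured fraction of
    them linked (same sign) to a differential TSS peak."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 4)
    gene_ids = [g.gene_id for g in genome.genes]
    n_rep = cfg.n_expr_samples_per_condition
    condition = ["control"] * n_rep + ["treated"] * n_rep
    sample_ids = [f"{c}_expr_{i % n_rep + 1}" for i, c in enumerate(condition)]

    n_de = int(round(cfg.de_fraction * len(gene_ids)))
    de_lfc = math.log2(cfg.de_effect_size)

    # genes whose TSS peak is differential, by sign
    peak_by_gene: dict[str, str] = {}
    if origins:
        for pid, o in origins.items():
            if o[0] == "tss":
                peak_by_gene[o[1]] = pid
    linked_pool = [
        (g, pid) for g, pid in peak_by_gene.items() if pid in truth.differential_log_fc
    ]
    rng.shuffle(linked_pool)

    chosen: dict[str, float] = {}
    for g, pid in linked_pool:
        if len(chosen) >= n_de:
            break
        if rng.random() < cfg.link_probability:
            sign = 1.0 if truth.differential_log_fc[pid] > 0 else -1.0
            chosen[g] = sign * de_lfc
            truth.linked_gene_peak[g] = pid
    remaining = [g for g in gene_ids if g not in chosen]
    idx = rng.choice(len(remaining), size=max(0, n_de - len(chosen)), replace=False)
    for i in idx:
        sign = 1.0 if rng.random() < cfg.de_up_fraction else -1.0
        chosen[remaining[i]] = sign * de_lfc
    truth.de_log_fc = dict(chosen)

    baseline = rng.normal(cfg.expr_baseline_mean, cfg.expr_baseline_sd, size=len(gene_ids))
    values = baseline[:, None] + rng.normal(
        0.0, cfg.expr_noise_sd, size=(len(gene_ids), 2 * n_rep)
    )
    treated = np.array([c == "treated" for c in condition])
    lfc = np.array([chosen.get(g, 0.0) for g in gene_ids])
    values += lfc[:, None] * treated[None, :]
    em = ExpressionMatrix(gene_ids, sample_ids, values, condition)
    return em, truth


# ---------------------------------------------------------------- study


def simulate_study(cfg: SimConfig) -> SimulatedStudy:
    """Run every generator stage off one seeded stream; fully deterministic."""
    rng = np.random.default_rng(cfg.seed)
    genome = generate_genome(cfg, rng)
    base, origins, sets = generate_peak_replicates(cfg, genome, rng)
    counts, truth = generate_counts(
        cfg, [p.peak_id for p in base], rng, origins=origins, hotspots=genome.hotspots
    )
    truth.planted_at_stretches = getattr(genome, "_truth_at", {})
    truth.planted_cpg = getattr(genome, "_cpg_island", None)
    tags = generate_tags(cfg, counts, base, genome, rng)
    expression, truth = generate_expression(cfg, genome, truth, origins, rng)
    return SimulatedStudy(cfg, genome, base, origins, sets, counts, tags, expression, truth)
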