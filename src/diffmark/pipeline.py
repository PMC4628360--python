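"""Config-driven end-to-end run over a dataset directory.

A dataset directory is described by a ``manifest.json`` (written by the
``simulate`` subcommand or by hand for real data) listing per-sample peak and
tag files with conditions and library sizes, the gene table, hotspot map,
chromosome sizes, genome FASTA, expression matrix and the PAR-like region.
``run_all`` executes differential peak calling, annotation, hotspot
association, sequence features, differential expression and integration,
writing TSV/BED outputs plus a ``summary.json``.  Outputs carry no
timestamps, so a rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .annotate import (
    AnnotationConfig,
    chromosome_distribution,
    classify_genic,
    ncrna_overlap,
    tss_fraction,
)
from .diff_expr import de_genes, integrate_with_peaks, shortlist, ExpressionMatrix
from .diff_peaks import DifferentialPeakSet, ReplicatePeakSets, run_differential_pipeline
from .genome_io import (
    GenomicInterval,
    Peak,
    read_bed,
    read_fasta,
    read_gene_table,
    read_hotspot_bed,
    write_bed,
)
from .hotspot_assoc import associate_hotspots, gene_hotspot_summary, intensity_compare, region_signal
from .seq_features import gene_feature_table
from .stats_core import scale_normalize

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "parse_region"]


@dataclass
class RunConfig:
    """All paths and thresholds for one pipeline run."""

    input_dir: str
    out_dir: str
    fc_cut: float = 1.5
    fdr_cut: float = 0.05
    quantile_cut: float = 0.05
    genic_flank: int = 1000
    tss_window: int = 1000
    at_min_len: int = 8
    min_overlap: int = 1
    de_fc_cut: float = 1.5
    de_p_cut: float = 0.05
    shortlist_fc: float = 2.0
    pseudocount: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.quantile_cut < 1):
            raise ValueError("quantile_cut must be in (0, 1)")
        if self.fc_cut < 1 or self.de_fc_cut < 1 or self.shortlist_fc < 1:
            raise ValueError("fold-change cutoffs must be >= 1")
        if not (0 < self.fdr_cut <= 1) or not (0 < self.de_p_cut <= 1):
            raise ValueError("significance cutoffs must be in (0, 1]")
        if min(self.genic_flank, self.tss_window) < 0 or self.at_min_len < 2:
            raise ValueError("window parameters out of range")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def parse_region(spec: str) -> GenomicInterval:
    """Parse ``chrom:start-end`` (0-based half-open) into an interval."""
    chrom, _, span = spec.partition(":")
    start, _, end = span.partition("-")
    return GenomicInterval(chrom, int(start), int(end))


def _load_tags(path) -> dict[str, np.ndarray]:
    by_chrom: dict[str, list[int]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                continue
            by_chrom.setdefault(fields[0], []).append(int(fields[1]))
    return {c: np.sort(np.asarray(v)) for c, v in by_chrom.items()}


def _region_peak_counts(cm, dps: DifferentialPeakSet, region: GenomicInterval) -> list[int]:
    """Per-sample sum of tag counts over consensus peaks inside ``region``.

    Peak-based counting keeps the comparison on the H3K4me3 signal itself;
    raw tag totals would mix in genome-wide background."""
    rows = [
        i for i, pid in enumerate(cm.feature_ids)
        if dps.peaks[pid].interval.overlap_bp(region) > 0
    ]
    if not rows:
        return [0] * len(cm.sample_ids)
    return cm.counts[rows, :].sum(axis=0).tolist()


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage the manifest supports; returns the summary dict.

    A stage whose inputs are absent from the manifest is skipped with a
    logged notice and recorded in the summary under ``skipped_stages``.
    """
    indir = Path(cfg.input_dir)
    outdir = Path(cfg.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(indir / "manifest.json") as fh:
        manifest = json.load(fh)

    summary: dict = {"version": __version__, "seed": cfg.seed, "thresholds": asdict(cfg)}
    skipped: list[str] = []
    cfg_echo = {k: v for k, v in asdict(cfg).items() if k != "out_dir"}
    log_lines = [f"diffmark {__version__}", f"seed {cfg.seed}",
                 f"config {json.dumps(cfg_echo, sort_keys=True)}"]

    # ------------------------------------------------ differential peaks
    samples = manifest["samples"]
    peak_sets = [read_bed(indir / s["peak_file"], dialect=s.get("dialect", "narrowPeak"))
                 for s in samples]
    tags = [_load_tags(indir / s["tag_file"]) for s in samples]
    sets = ReplicatePeakSets(
        peak_sets,
        [s["condition"] for s in samples],
        [float(s["library_size"]) for s in samples],
        sample_ids=[s["id"] for s in samples],
    )
    dps, cm, nm = run_differential_pipeline(
        sets, tag_positions=tags, min_overlap=cfg.min_overlap,
        quantile_cut=cfg.quantile_cut, fc_cut=cfg.fc_cut, fdr_cut=cfg.fdr_cut,
        pseudocount=cfg.pseudocount,
    )
    called_peaks = [
        Peak(dps.peaks[r.feature_id].interval, r.feature_id) for r in dps.called
    ]
    _write_differential_tsv(dps, outdir / "differential_peaks.tsv")
    write_bed(called_peaks, outdir / "called_peaks.bed", dialect="bed3")
    summary.update(
        n_consensus=len(dps.peaks), n_tested=len(dps.results),
        n_differential=len(dps.called), n_up=dps.n_up, n_down=dps.n_down,
    )
    log_lines.append(f"diffpeaks: {len(dps.called)} called ({dps.n_up} up, {dps.n_down} down)")

    # ------------------------------------------------ annotation
    genes = read_gene_table(indir / manifest["genes"]) if "genes" in manifest else None
    acfg = AnnotationConfig(cfg.genic_flank, cfg.tss_window)
    if genes is not None:
        labels, asum = classify_genic(called_peaks, genes, acfg)
        frac_tss = tss_fraction(called_peaks, genes, acfg)
        nc_rows = ncrna_overlap(called_peaks, genes)
        chrom_sizes = _read_chrom_sizes(indir / manifest["chrom_sizes"])
        dist, corr = chromosome_distribution(called_peaks, chrom_sizes)
        summary.update(
            n_genic=asum.n_genic, n_intergenic=asum.n_intergenic,
            pct_genic=round(100.0 * asum.n_genic / max(1, len(called_peaks)), 1),
            pct_tss=round(100.0 * frac_tss, 1),
            n_ncrna=len({r["peak_id"] for r in nc_rows}),
            chrom_length_correlation=None if math.isnan(corr) else round(corr, 4),
        )
        _write_annotation(labels, nc_rows, dist, acfg, outdir)
        log_lines.append(f"annotate: {asum.n_genic} genic / {asum.n_intergenic} intergenic")
    else:
        skipped.append("annotate")
        log.info("no gene table in manifest; annotation skipped")

    # ------------------------------------------------ hotspot association
    if "hotspots" in manifest and genes is not None:
        hotspots = read_hotspot_bed(indir / manifest["hotspots"])
        assoc = associate_hotspots(called_peaks, hotspots, genes,
                                   min_overlap=cfg.min_overlap, cfg=acfg)
        summary.update(
            n_hotspot_associated=assoc.n_associated_peaks,
            n_hotspot_within_genes=assoc.n_within_genes,
        )
        if assoc.n_associated_peaks:
            med_a, med_all, p = intensity_compare(assoc, hotspots)
            summary.update(
                hotspot_median_log_tags_assoc=round(med_a, 4),
                hotspot_median_log_tags_all=round(med_all, 4),
                hotspot_intensity_p=float(f"{p:.3g}"),
            )
        rows = gene_hotspot_summary(genes, hotspots, min_overlap=cfg.min_overlap)
        _write_tsv(outdir / "gene_hotspots.tsv", rows,
                   ["gene_id", "length_mb", "n_dsb", "highest_dsb_signal"])
        log_lines.append(f"hotspots: {assoc.n_associated_peaks} associated peaks")
    else:
        skipped.append("hotspots")
        log.info("no hotspot map in manifest; hotspot stage skipped")

    # ------------------------------------------------ PAR-like region signal
    if "par_region" in manifest:
        region = parse_region(manifest["par_region"])
        rcounts = _region_peak_counts(cm, dps, region)
        rs = region_signal(rcounts, region, cm.library_sizes, cm.condition)
        summary.update(
            par_region=manifest["par_region"],
            par_mean_control=round(rs.mean_control, 3),
            par_mean_treated=round(rs.mean_treated, 3),
            par_ratio=None if rs.ratio is None else round(rs.ratio, 4),
        )
        log_lines.append(f"region: PAR ratio {summary.get('par_ratio')}")
    else:
        skipped.append("region")

    # ------------------------------------------------ sequence features
    if "fasta" in manifest and genes is not None:
        fasta = read_fasta(indir / manifest["fasta"])
        big = [g for g in genes if len(g.interval) >= 500_000]
        rows = gene_feature_table(big, fasta, min_len=cfg.at_min_len)
        _write_tsv(
            outdir / "gene_features.tsv",
            [asdict(r) for r in rows],
            ["region_id", "length_bp", "at_fraction", "n_at_stretches", "n_cpg"],
            header_comment=f"at_stretch_min_len={cfg.at_min_len}",
        )
        summary["n_large_genes_profiled"] = len(rows)
        log_lines.append(f"seqfeat: {len(rows)} large genes profiled")
    else:
        skipped.append("seqfeat")

    # ------------------------------------------------ expression + integration
    if "expression" in manifest and genes is not None:
        em = _read_expression(indir / manifest["expression"])
        de = de_genes(em, fc_cut=cfg.de_fc_cut, p_cut=cfg.de_p_cut)
        called_genes = [r for r in de if r.direction != "ns"]
        short = shortlist(de, fc_cut=cfg.shortlist_fc)
        summary.update(n_de_genes=len(called_genes), n_shortlist=len(short))
        _write_de_tsv(de, outdir / "de_genes.tsv")
        (outdir / "shortlist.txt").write_text("".join(g + "\n" for g in short))

        scaled, _ = scale_normalize(cm)
        cond = np.asarray(cm.condition)
        peak_signal = {
            pid: (dps.peaks[pid].interval,
                  float(scaled[i, cond == "control"].mean()),
                  float(scaled[i, cond == "treated"].mean()))
            for i, pid in enumerate(cm.feature_ids)
        }
        records = integrate_with_peaks(de, peak_signal, genes, tss_window=cfg.tss_window)
        _write_integration(records, outdir / "integration.tsv")
        n_nd = sum(r.nd for r in records)
        summary.update(n_integrated=len(records), n_integration_nd=n_nd)
        log_lines.append(f"diffexpr: {len(called_genes)} DE genes, {n_nd} ND at TSS")
    else:
        skipped.append("diffexpr")

    summary["skipped_stages"] = skipped
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    (outdir / "run.log").write_text("".join(l + "\n" for l in log_lines))
    return summary


# ---------------------------------------------------------------- writers


def _read_chrom_sizes(path) -> dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            fields = line.split("\t")
            if len(fields) >= 2:
                sizes[fields[0]] = int(fields[1])
    return sizes


def _read_expression(path) -> ExpressionMatrix:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    condition = ["control" if c.startswith("control") else "treated" for c in df.columns]
    return ExpressionMatrix(list(df.index), list(df.columns), df.to_numpy(), condition)


def _write_differential_tsv(dps: DifferentialPeakSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("peak_id\tchrom\tstart\tend\tlog_fc\tfc\tt\tp\tq\tdirection\tsource\n")
        for r in dps.results:
            c = dps.peaks[r.feature_id]
            iv = c.interval
            fh.write(
                f"{r.feature_id}\t{iv.chrom}\t{iv.start}\t{iv.end}\t"
                f"{r.log_fc:.4f}\t{r.fc:.4f}\t{r.t_stat:.4f}\t{r.p_value:.4g}\t"
                f"{r.q_value:.4g}\t{r.direction}\t{c.source}\n"
            )


def _write_de_tsv(results, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tlog_fc\tfc\tt\tp\tdirection\n")
        for r in results:
            fh.write(
                f"{r.feature_id}\t{r.log_fc:.4f}\t{r.fc:.4f}\t{r.t_stat:.4f}\t"
                f"{r.p_value:.4g}\t{r.direction}\n"
            )


def _write_integration(records, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tfc_expression\tfc_chip\ttss_peaks\n")
        for r in records:
            chip = "ND" if r.fc_chip is None else f"{r.fc_chip:.2f}"
            fh.write(f"{r.gene_id}\t{r.fc_expression:.2f}\t{chip}\t{','.join(r.tss_peak_ids)}\n")


def _write_tsv(path, rows: list[dict], columns: list[str], header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(row[c]) for c in columns) + "\n")


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.4f}"
    return "" if v is None else str(v)


def _write_annotation(labels, nc_rows, dist, acfg: AnnotationConfig, outdir: Path) -> None:
    with open(outdir / "peak_annotation.tsv", "w") as fh:
        fh.write(f"# genic_flank={acfg.genic_flank} tss_window={acfg.tss_window}\n")
        fh.write("peak_id\tlabel\n")
        for pid in sorted(labels):
            fh.write(f"{pid}\t{labels[pid]}\n")
    _write_tsv(
        outdir / "ncrna_overlap.tsv", nc_rows,
        ["peak_id", "ncrna_id", "upstream_gene", "upstream_distance",
         "downstream_gene", "downstream_distance"],
    )
    with open(outdir / "chromosome_distribution.tsv", "w") as fh:
        fh.write("chrom\tn_peaks\tpercent\n")
        for chrom in sorted(dist):
            n, pct = dist[chrom]
            fh.write(f"{chrom}\t{n}\t{pct:.2f}\n")
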