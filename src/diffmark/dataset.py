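"""Serialise a simulated study to a dataset directory the pipeline can run.

Layout written by :func:`write_study`::

    <dir>/manifest.json        sample table + file paths + PAR region
    <dir>/<sample>.narrowPeak  per-replicate peak calls
    <dir>/tags_<sample>.bed    per-sample single-base tag positions
    <dir>/genes.tsv            gene table
    <dir>/hotspots.bed         BED4 hotspot map (col 4 = DMC1 tags)
    <dir>/chrom.sizes          two-column chromosome sizes
    <dir>/genome.fa            chromosome sequences
    <dir>/expression.tsv       log2 expression matrix (genes x samples)
    <dir>/truth_peaks.tsv      injected per-peak log2 fold changes
    <dir>/truth_genes.tsv      injected per-gene log2 fold changes
"""

from __future__ import annotations

import json
from pathlib import Path

from .genome_io import write_bed, write_fasta, write_gene_table, write_hotspot_bed
from .synthetic import SimulatedStudy

__all__ = ["write_study"]


def write_study(study: SimulatedStudy, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sets = study.replicate_sets
    samples = []
    for i, sid in enumerate(sets.sample_ids):
        peak_file = f"{sid}.narrowPeak"
        tag_file = f"tags_{sid}.bed"
        write_bed(sets.peak_sets[i], outdir / peak_file, dialect="narrowPeak")
        with open(outdir / tag_file, "w") as fh:
            for chrom in sorted(study.tags[i]):
                for pos in study.tags[i][chrom]:
                    fh.write(f"{chrom}\t{pos}\t{pos + 1}\n")
        samples.append(
            {
                "id": sid,
                "condition": sets.condition[i],
                "library_size": sets.library_sizes[i],
                "peak_file": peak_file,
                "tag_file": tag_file,
                "dialect": "narrowPeak",
            }
        )

    write_gene_table(study.genome.genes, outdir / "genes.tsv")
    write_hotspot_bed(study.genome.hotspots, outdir / "hotspots.bed")
    with open(outdir / "chrom.sizes", "w") as fh:
        for chrom, size in study.genome.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")
    if study.genome.sequences:
        write_fasta(study.genome.sequences, outdir / "genome.fa")

    em = study.expression
    with open(outdir / "expression.tsv", "w") as fh:
        fh.write("gene_id\t" + "\t".join(em.sample_ids) + "\n")
        for g, row in zip(em.gene_ids, em.values):
            fh.write(g + "\t" + "\t".join(f"{v:.4f}" for v in row) + "\n")

    par = study.genome.par_region
    manifest = {
        "samples": samples,
        "genes": "genes.tsv",
        "hotspots": "hotspots.bed",
        "chrom_sizes": "chrom.sizes",
        "expression": "expression.tsv",
        "par_region": f"{par.chrom}:{par.start}-{par.end}",
    }
    if study.genome.sequences:
        manifest["fasta"] = "genome.fa"
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    truth = study.truth
    with open(outdir / "truth_peaks.tsv", "w") as fh:
        fh.write("peak_id\tlog_fc\tkind\n")
        for pid in sorted(truth.differential_log_fc):
            kind = "par" if pid in set(truth.par_peak_ids) else (
                "hotspot" if pid in truth.hotspot_linked_peaks else "injected"
            )
            fh.write(f"{pid}\t{truth.differential_log_fc[pid]:.4f}\t{kind}\n")
    with open(outdir / "truth_genes.tsv", "w") as fh:
        fh.write("gene_id\tlog_fc\tlinked_peak\n")
        for g in sorted(truth.de_log_fc):
            fh.write(
                f"{g}\t{truth.de_log_fc[g]:.4f}\t{truth.linked_gene_peak.get(g, '')}\n"
            )
    return outdir
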