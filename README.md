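# diffmark

Replicate-aware differential histone-mark peak analysis for two-condition
ChIP-seq designs, built around the H3K4me3 mark in mouse testis: which
promoter/recombination-associated trimethylation peaks change under a
treatment, where those changes sit in the genome, whether they coincide with
meiotic double-strand-break (DSB) hotspots, and how they relate to
expression changes measured on arrays.

The package is aimed at analysts who already have per-replicate peak calls
(MACS-style narrowPeak/BED) and mapped-tag positions, and want the
downstream statistics reproducible and testable: every stage is a library
function, every input format is plain text, and a synthetic-data generator
produces complete ground-truth-labelled studies so the whole pipeline can be
validated without any external download.

## The procedure

Differential peaks are called in fixed stages:

1. **Reproducibility.** Within each condition, keep peaks supported by both
   biological replicates (≥ 1 bp overlap by default; intervals extended to
   the union span of the matched pair).
2. **Consensus.** Merge the control- and treated-reproducible sets into
   disjoint consensus intervals; these are the units of testing.
3. **Quantification + normalization.** Count tags per consensus peak and
   sample, multiply each sample by a scale factor (target depth / library
   size) to equalize effective depth, then transform to
   log2(scaled count + 1).
4. **Quantile filter.** Drop peaks whose mean normalized value across all
   samples is not above the 5 % nearest-rank quantile.
5. **Moderated test.** Empirical-Bayes moderated t-statistic per peak:

       s̃²_g = (d₀ s₀² + d_g s²_g) / (d₀ + d_g)
       t_g  = (x̄_treated − x̄_control) / (s̃_g √(1/n₁ + 1/n₂))

   with the prior (d₀, s₀²) fitted by moments on log sample variances and
   t_g referred to a t distribution on d₀ + d_g df. A peak is called
   differential iff its linear fold change exceeds 1.5 **and** its
   Benjamini–Hochberg q-value is below 0.05.

Around the core test, the package annotates called peaks (genic/intergenic
with a ±1 kb flank, TSS windows, ncRNA overlap, per-chromosome counts vs
chromosome length), associates them with DSB hotspot maps (BED4 with DMC1
tag counts; intensity compared as log(#tags) with a rank-sum test), compares
region-level signal such as the X-chromosome pseudoautosomal region (PAR),
scans gene sequences for AT content / AT stretches / CpG counts, calls
array-style differential expression (moderated t, |FC| > 1.5, raw p < 0.05),
and joins ChIP and expression fold changes at gene TSSs.

## Worked example

Simulate a study and run everything:

```bash
diffmark simulate --seed 1 --out demo_data
diffmark all --input demo_data --out demo_out
```

`demo_out/summary.json` from this exact invocation contains (among others):

```
"n_consensus": 1942,   # consensus peaks tested
"n_differential": 89,  # called at FC > 1.5 and q < 0.05
"n_up": 79,  "n_down": 10,
"pct_genic": 55.1,     # called peaks within genes ± 1 kb
"n_hotspot_associated": 34,
"hotspot_median_log_tags_assoc": 5.5549,  # vs 4.0342 over all hotspots
"par_ratio": 0.5217,   # treated/control H3K4me3 signal in the PAR-like region
"n_de_genes": 25
```

Read: of 1942 reproducible consensus peaks, 89 changed, with the strong
up-bias the generator injects (97:3); the hotspot-associated subset sits on
markedly hotter DSB hotspots than average (median log tags 5.55 vs 4.03);
and the PAR-like region lost about half its signal in the treated condition
(its injected ratio is 0.5). The per-peak table is in
`demo_out/differential_peaks.tsv`, called intervals in
`demo_out/called_peaks.bed`.

## Layout

- `src/diffmark/genome_io.py` — interval types, BED/narrowPeak/FASTA/TSV readers, overlap kernel
- `src/diffmark/stats_core.py` — normalization, moderated t, BH FDR, chi-square, hypergeometric enrichment, rank-sum
- `src/diffmark/diff_peaks.py` — reproducibility → consensus → quantify → filter → call
- `src/diffmark/annotate.py` — genic/TSS/ncRNA/chromosome annotation
- `src/diffmark/hotspot_assoc.py` — DSB hotspot association, intensity and region signal
- `src/diffmark/seq_features.py` — AT content, AT stretches, CpG counts
- `src/diffmark/diff_expr.py` — array-style DE and ChIP/expression integration
- `src/diffmark/synthetic.py` — ground-truth study generator
- `src/diffmark/pipeline.py`, `cli.py` — orchestration and the `diffmark` command

See `docs/methods.md` for the statistical model, generator design and known
limitations.
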