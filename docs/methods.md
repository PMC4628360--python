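# Methods

## Coordinates and overlap semantics

All intervals are 0-based half-open `[start, end)`, the native convention of
BED and narrowPeak. Intervals touching at a single coordinate share no base
and never overlap. Chromosome names are compared as exact strings; no
`chr`-prefix normalization is attempted. Strand is ignored for peak overlap
(histone marks are unstranded) and used only to place a gene's TSS (`start`
on `+`, `end − 1` on `−`). The default minimum overlap for every
"overlapping" claim is 1 bp — the permissive convention; it is configurable
(`min_overlap`) everywhere it matters, and hotspot-association counts are
monotone non-increasing in it.

## Differential peak model

The unit of testing is the **consensus peak**: within each condition, a peak
is reproducible when it overlaps a peak of the other biological replicate;
the kept interval is the union span of the matched peaks, so replicate
boundary jitter cannot clip signal. Reproducible sets of both conditions are
merged into disjoint consensus intervals. Reproducibility by overlap is a
deliberate simplification of copula-based irreproducible-discovery-rate
screening: with two replicates per condition, a 1-bp-overlap rule is
transparent, deterministic, and testable against a set-algebra oracle.

Counts are tags whose position falls inside a consensus interval; library
size is the total tag count of the sample (tags on peak-free chromosomes
still count toward depth). Normalization multiplies each sample by
`target / library_size`, with `target` defaulting to the mean library size —
the choice only shifts the log scale by a constant and cancels from every
two-group statistic. The test substrate is `log2(scaled + 1)`; the
pseudocount (default 1, configurable) keeps zeros finite and is deliberately
small relative to typical peak counts.

The **quantile filter** computes per-peak means across all samples and
retains peaks strictly above the nearest-rank (type-1) q-quantile
(default q = 0.05). Strictness follows from filtering "above" the quantile;
an all-tied input would retain nothing and is rejected with a message rather
than silently passed through. The filter sees only consensus peaks — its
threshold is a property of the reproducible set, not of raw peak calls.

The **moderated t-statistic** shrinks each peak's pooled two-group variance
`s²_g` (d_g = n₁ + n₂ − 2 df) toward a prior `s0²` with weight `d0`:

    s̃²_g = (d0·s0² + d_g·s²_g) / (d0 + d_g)
    t_g   = Δ_g / (s̃_g · sqrt(1/n₁ + 1/n₂)),   df = d0 + d_g

Hyperparameters are fitted by moments on z_g = log s²_g: under the scaled-F
hierarchy, E[z] and Var[z] involve digamma/trigamma terms in d_g and d0, so
d0 is the trigamma inverse of the excess spread of z and s0² follows from
the corrected mean. When the spread does not exceed the trigamma floor
ψ′(d_g/2), the variances are consistent with a single common value: d0 = ∞
and s0² is the arithmetic mean of the sample variances (the unbiased
raw-scale estimator; this matches the current limma `fitFDist` behaviour,
which the test suite cross-checks via Rscript). At d0 = ∞ the reference
distribution is the exact normal limit; limma instead caps the total df at
the summed residual df, a difference of under ~6 % in p-values at t ≈ 2.5
that the cross-check test accounts for explicitly.

A peak is called differential iff `2^|log2FC| > 1.5` **and** BH q < 0.05,
with direction from the sign of the fold change. Thresholds mirror the
analysis this package reimplements and are configurable. Fold changes are
reported both as log2 and linear values, since results tables
conventionally print linear ratios.

### Power under the default simulation conditions

Under the generator defaults (2000 peaks, 5 % differential at linear FC 3,
NB dispersion 0.05, mean depth 50, 2 vs 2 replicates), the per-peak log2
variance is ≈ (1/m + φ)/ln²2 ≈ 0.14, giving a typical moderated t around 4.
Against the BH-adjusted significance boundary this yields a mean recall of
≈ 0.69 and a mean false-discovery proportion of ≈ 0.06 over 50 simulations.
This is the ceiling of the stated conditions, not an implementation loss:
limma applied to the identical normalized matrices produces the same calls
(maximum p-value discrepancy < 0.2 %). Recall rises with depth or falls
with dispersion; the asymmetry of calls (up ≫ down) is recovered in every
simulation.

## Annotation

Genic means overlapping any gene body extended by `genic_flank` (default
1 kb) on both sides; intergenic is the complement, and the two always
partition the called set (asserted at run time). "At a TSS" means
overlapping the symmetric window `[tss − w, tss + w)`, default w = 1 kb,
chosen for consistency with the genic flank and printed in output headers.
ncRNA overlap uses the bare gene body, no flank, and reports the nearest
coding gene on each side of the peak midpoint. Categories are non-exclusive
counters. Per-chromosome counts are accompanied by the Pearson correlation
between count and chromosome length.

## Hotspot association and region signal

A differential peak is hotspot-associated when it overlaps a DSB hotspot
record (BED4; column 4 = DMC1 SSDS tag count). Intensities are compared as
natural-log tag counts — per-hotspot totals, not per-bp densities — between
the associated subset and the full map, with a Mann–Whitney rank-sum
p-value (midranks for ties; the p-value is invariant to any monotone
rescaling of tags). Zero-tag hotspots are excluded from log-scale medians
with a logged count.

Region signal (used for the PAR-like region) is the per-condition mean of
scale-normalized counts inside the region, reported with the
treated/control ratio; a zero control mean flags the ratio undefined rather
than returning infinity. The pipeline feeds it the summed counts of
consensus peaks inside the region, so the ratio measures the mark itself
rather than genome-wide background tags. PAR coordinates are configuration
values, never hard-coded.

## Sequence features

AT content is (A+T)/(A+C+G+T) with ambiguous bases excluded from the
denominator; it is reverse-complement invariant by construction. An AT
stretch is a maximal run of A/T of length ≥ `min_len`; any other character
breaks a run. There is no community-standard stretch length, so `min_len`
is an explicit, reported parameter (default 8) — composition tables are
reproducible only together with this choice, which is printed in output
headers. CpG counting is the literal count of `CG` dinucleotides
(orientation-sensitive on one strand, but the total is reverse-complement
invariant since CpG is its own reverse complement). Soft-masked lowercase
bases are uppercased before counting.

## Differential expression and integration

Expression input is a gene × sample matrix of log2 intensities (3 vs 3 by
default). The same moderated t is applied; genes are called at linear
|FC| > 1.5 and **raw** p < 0.05 — raw rather than adjusted, matching the
array-analysis convention this reimplements — with an optional shortlist at
|FC| ≥ 2 (inclusive). Integration finds, for each called gene, the consensus
peaks overlapping its ±1 kb TSS window and reports the ratio of mean
normalized treated to control signal averaged over those peaks; genes with
no nearby peak are reported as `ND`, mirroring how such rows are printed in
results tables. Every resolvable called gene yields exactly one record.

## Synthetic studies

The generator emulates the study design end to end from a single seed:

- **Genome**: 6 chromosomes, linearly decreasing lengths (6 → 2 Mb), the
  last (`chrX`) carrying a 400-kb PAR-like terminal region with a planted
  CpG island of exactly 127 CpGs. Genes are packed without overlap
  (exponential lengths, mean 20 kb; 15 % ncRNA); five "very large" genes
  (0.5–1.1 Mb) are placed on autosomes and built from AT-rich sequence
  (62 % AT vs 50 % background) with planted, G/C-isolated AT stretches.
- **Hotspots**: counts per chromosome proportional to length; DMC1 tags
  log-normal (μ = 4, σ = 1.2), giving the heavy right tail real SSDS maps
  show.
- **Peaks**: placed over gene TSSs (p = 0.7), on hotspots sampled
  proportionally to their tag counts, inside the PAR, and as background
  fill to 2000, all mutually separated by more than twice the replicate
  jitter so consensus intervals map one-to-one onto base peaks. Replicates
  observe the base peaks with independent dropout (0.1) and ±30 bp boundary
  jitter.
- **Counts**: negative binomial with Var = m + φm² (φ = 0.05), per-peak
  baseline depths log-normal around 50 tags, library sizes deliberately
  imbalanced (0.7–1.3 × 10⁶). Five percent of peaks are differential at
  linear FC 3 with a 97:3 up:down ratio; a block of the differential peaks
  is drawn from hotspot-linked peaks weighted by DMC1 intensity (all up,
  emulating elevation at the strongest hotspots); every peak inside the
  PAR-like region carries the region ratio 0.5 in the treated condition.
- **Tags**: counts realized as uniform positions within each peak plus 20 %
  genome-wide background, so the file-level pipeline (quantify from tag
  BEDs) is exercised, not just the count matrices.
- **Expression**: Gaussian log2 intensities (noise sd 0.25), 5 % DE genes at
  linear FC 2; with probability 0.8 a DE gene is linked to a same-sign
  differential TSS peak, creating the agreement structure the integration
  stage reports.

What the generator does **not** emulate: read-level artifacts (mappability,
GC bias, fragment-length effects), peak-shape differences, batch effects,
and biological covariance between neighbouring peaks. Passing recovery
tests therefore demonstrates the statistical pipeline is correct and
calibrated under its own model assumptions, not that those assumptions hold
for any particular real dataset.

## Numerical and engineering choices

- Trigamma inversion by Newton iteration from Smyth's starting value
  `0.5 + 1/y`; convergence tolerance 1e-10 relative.
- Zero pooled variance with d0 = 0 yields ±∞ t (p = 0) for a real shift and
  t = 0 otherwise, rather than NaN.
- BH is implemented directly (sort, step-up, reverse cumulative minimum,
  cap at 1) and cross-checked against statsmodels in tests; note that
  re-applying BH to already-adjusted values does *not* preserve the
  rejection set in general, so the tested invariant is the equivalence of
  `{q ≤ α}` with the classic step-up rejection set.
- All randomness flows through one `numpy` Generator seeded from the
  config; two runs with the same seed are byte-identical, and output files
  carry no timestamps.
- Problem sizes in the test suite (tiny 3-chromosome studies for pipeline
  tests; 2000-peak count matrices for calibration checks; 50–200 simulation
  repeats) were chosen so the whole suite validates the statistical claims
  in a few seconds to minutes while keeping Monte-Carlo error well inside
  the asserted tolerances.

## Known limitations

- Reproducibility screening is overlap-based; it does not rank-match peak
  signal between replicates as IDR does.
- The moderated test assumes approximately Gaussian log-scale noise; at
  very low depth (< ~10 tags) the NB-to-lognormal approximation degrades.
- The quantile filter is global, not condition-wise; a peak silenced in one
  condition but strong in the other is retained (by design).
- CpG-island *detection* is out of scope; only CpG counting over given
  regions is provided.
- Probe-to-gene mapping for arrays is out of scope; expression input is
  gene-level.
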