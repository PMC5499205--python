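# Methods

This note documents the models, parameter choices and numerical conventions
behind `dsbmap`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Coordinates and formats

All interval arithmetic is 0-based half-open. BED is the native dialect
(BED6 for sites and reads, BED12 for gene models with exon blocks, bedGraph
for fixed-width window counts); SAM/BAM reads are converted to internal read
records at the boundary (barcode from the `BC` tag, UMI from `RX`). For a
minus-strand read the 5′ end — the break-proximal end in BLISS chemistry —
is the last aligned base.

## In silico digestion

The AsiSI recognition motif GCGATCGC is an 8-bp palindrome, so a single
forward-strand scan enumerates every genomic occurrence; overlapping
occurrences are all reported because digestion is defined per recognition
occurrence. Matching is case-insensitive, so soft-masked assemblies digest
identically to unmasked ones. IUPAC ambiguity codes in the motif are
supported behind an explicit flag. Each site's quantification window is
`[center − flank, center + flank)` with `center = motif_start + 4` (the
motif midpoint; windows are symmetric around the recognition sequence) and
`flank = 100 bp` by default. Site density is reported both pooled (total
sites / total Mb) and as the per-chromosome mean, since either averaging is
defensible. For assembly-scale genomes the FASTA is streamed record by
record. Reference chromosomes are chr1–22, X, Y, M; all other records count
as haplotype/unplaced.

## BLISS quantification and ranking

Reads are filtered by linker barcode (Hamming distance ≤ `max_mismatch`,
default 1; wrong-length or missing barcodes are dropped and counted) and
deduplicated on `(chrom, start, strand, UMI)`.

Per site and library: `cf` is the fraction of window bases covered by the
union of read spans (full fragment spans when mate information is present);
`rc` has two modes. The default `pileup-origin` mode sums the per-base depth
inside the window contributed by reads whose 5′ end lies in the window. The
alternative `starts` mode counts those reads. The pileup mode is the default
for ranking because it is numerically robust where the count mode is not:
with count `rc`, a single read clipping a window edge yields a tiny `cf` and
an exploding `ln = rc/cf` (a 2 bp overlap turns one read into
`ln = 100`), whereas under pileup `rc` the overlap cancels and any single
read contributes `ln =` window length, far below a genuinely cut site. The
instability only matters for sparse libraries (an uninduced control has
~0.02 background reads per window here) but there it dominates the ranking.
Both modes are selectable in the pipeline configuration.

`ln = rc/cf` (0 where `cf = 0`: no reads, no evidence), `gn = ln /
median(ln)` with midpoint interpolation for even counts, which makes
`median(gn) = 1` exact. A library whose median `ln` is zero carries no
signal at the inspected sites; standalone normalization raises on it, but
the paired ranking chain instead places *both* libraries on the
non-degenerate companion's median (a shared scale, so the pseudocount means
the same thing in both) and skips quantile normalization, since rank-mapping
onto a near-empty distribution would erase the induced signal. Otherwise,
quantile normalization maps the induced `gn` distribution rank-for-rank onto
the uninduced one (uninduced never changes); tied induced entries receive
the mean of the uninduced values at the tied ranks, the one case where the
sorted multisets of the two outputs can differ.

Ranking uses `log2[(qn_i + ε)/(qn_u + ε)]` with ε = 1, descending, ties
broken by genomic coordinate. A site is called when the log2 ratio is ≥ 1
and at least 3 reads originate in the induced window (the read-count
threshold always uses the origin-read count, independent of the `rc` mode).
The cutoff/ε/min-read defaults are calibrated on the synthetic scenario and
fully configurable; no published threshold exists for this chain.

## γH2AX domains and per-site scores

Window counts (250 bp default) are z-scored against a background estimated
from the trimmed distribution (top 1% of windows excluded; a Poisson option
with σ = √μ exists). The enrichment threshold is strict (z > 3). Adjacent
qualifying windows fuse into one peak ("windows or multiples thereof");
peaks merge into clusters when midpoints are ≤ n apart, chained
transitively — on a line this is exactly the connected components of the
midpoint-distance graph, so the result is independent of input order. The
default n = 2,000 bp is configurable; no published value exists.

The per-site rank score is a documented surrogate (the original analysis
names a rank score without defining it): log2 of the induced/uninduced RPM
ratio over `[center ± 5 kb]` excluding `[center ± 1 kb]`, the exclusion
matching the coverage dip observed at breaks, with ε = 1 RPM. RPM
normalization makes the score invariant under duplicating every read. The
top K = 100 sites (or all sites, with a warning, when fewer exist) are the
γH2AX candidates; their intersection with the BLISS calls is the
gold-standard set, reported with per-site provenance (bliss_only /
h2ax_only / both). Input-library subtraction is out of scope; enrichment is
induced-vs-uninduced only.

## Expression impact

Sites are assigned to genes when the site center falls within the gene span
± 2 kb; distance is measured from the site center to the nearest gene edge
(0 inside). Location classes: `promoter_tss` for sites ≤ 2 kb upstream of
the TSS (strand-aware) or inside 5′-UTR exonic sequence (exons upstream of
the CDS, when BED12 thick coordinates are present), `gene_body` elsewhere
inside the gene, `intergenic` otherwise; without CDS annotation the rule
falls back to position only.

Fold changes are a deliberate simplification of a regularized-log contrast:
median-of-ratios size factors (CPM optional), pseudocount 1, log2,
replicates averaged on the log scale, induced − uninduced. A variance-
stabilizing transform is *not* re-implemented; at the count depths simulated
here the difference is small except at very low counts, where the
pseudocount plays the shrinkage role. The size factors can be restricted to
a control-gene set: when a non-negligible fraction of genes shifts in one
direction, all-gene median-of-ratios absorbs part of the shift (a ~0.05
log2 bias with 10% of genes repressed, as in the toy scenario; negligible
in a real transcriptome where the affected fraction is far smaller). The
recovery analyses therefore normalize on genes farther than 100 kb from any
site.

The shift test is a one-sided ("less") Wilcoxon rank-sum. For
n₁·n₂ ≤ 10⁴ the exact tie-aware permutation distribution is computed by
dynamic programming over (subset size, doubled midrank sum) — this equals
full enumeration of label assignments, ties included, which scipy's exact
method does not provide; larger problems use scipy's tie-corrected normal
approximation with continuity correction. ECDFs of both groups are returned
for cumulative-distribution plots.

Metagene profiles length-normalize each gene body (TSS→TES, reversed for
minus-strand genes, exon-concatenated when splicing is simulated) into
equal-count bins, then average across genes with standard errors, scaled by
1e6/library size (RPM). Genes shorter than the bin count are skipped with a
warning.

Distance decay bins genes by distance to the nearest called site: cumulative
"up to" bins at 0.1/1/100/1000 kb, a disjoint variant with a final open
bin, and constant-width 200 kb bins — both cumulative and disjoint are
emitted because either reading of the published figure is defensible. Bin
means come with standard errors; a weighted linear fit of bin mean against
log10(bin upper edge), weighted by gene counts, summarizes the trend, with
empty bins excluded. A separate estimator grid-searches the generative form
`logFC = −b · a_g · exp(−d/λ)` (amplitude per gene optional, e.g. the
nearest site's cutting efficiency) with the closed-form least-squares
amplitude per candidate λ.

TSS expression classes: per-TSS z-scaled expression across libraries is
clustered with k-means (k = 8, 25 restarts, fixed seed; cluster labels are
canonicalized by sorting on mean induced-minus-uninduced scaled change so
runs are comparable), clusters collapse into down/up/unchanged at ±0.25
scaled units (a free parameter; the published classes were assigned by
inspection), and a one-sided Fisher's exact test asks whether the down
class is enriched for TSSs with a cut site within ±2 kb. Gene proximity of
cut sites is tested against the binomial background p₀ = fraction of the
genome within a gene ± 2 kb (union of flanked gene spans).

Only single planned contrasts are run by default; when a condition grid
produces several tests per gene set, Benjamini–Hochberg correction should
be applied to the resulting p-value family (statsmodels
`multipletests(method="fdr_bh")`).

## Synthetic-data generator

The generator is first-class, tested code; its defaults define the study
conditions used by the recovery tests.

*Genome geometry.* Two chromosomes (6 Mb + 4 Mb) of uniform random sequence;
spontaneous motif occurrences are destroyed by single-base edits (never
touching planted copies) and exactly `n_sites = 20` motifs are planted.
Sites are confined to the first half of each chromosome with ≥ 100 kb
separation while genes span the whole genome, so gene-to-site distances
cover every decade from 0 to beyond 1 Mb — necessary for the distance-decay
analysis, and a ratio-preserving miniature of the real geometry (detected
cut sites are ~14 Mb apart against ~1 Mb domain spreading; here ~500 kb
against a 30 kb spreading half-width).

*Sites.* Half of the planted sites are cut (`fraction_cut = 0.5`), mirroring
that only a minority of genomic recognition sites is cleaved in vivo; cut
efficiencies e_s are uniform on [0.2, 1] (robustly cut sites, as the
published positive controls are). 80% of sites get a host gene overlapping
or within 2 kb, matching the observed gene proximity of detected sites.

*Genes.* 250 genes of 2–20 kb with 2–5 exons and a CDS; 100 of them are
placed at log-uniform distances (1 kb – 2.5 Mb) from randomly chosen sites
so that every distance decade is populated; the rest are uniform. Baseline
expression is log-normal (ln-mean 5.0, ln-sd 0.8).

*BLISS reads.* Per cut site, Poisson(50 · e_s) break-end reads with 5′ ends
falling in the ±100 bp window under a triangular falloff from the center
(the within-window distribution is not constrained by data; any shape could
be substituted), plus uniform background at 0.1 reads/kb in both libraries;
the uninduced library is background only. Reads are 50 bp, carry the 8-bp
linker barcode with per-base error 0.005 and a random 8-bp UMI.

*γH2AX coverage.* Expected window counts are background (5 per 250 bp
window) plus, per cut site, the kernel
`e_s · 50 · exp(−|x−c|/30 kb) · (1 − exp(−|x−c|/1 kb))` — exponential
spreading with a central dip — truncated at 5 spreading half-widths, with
Poisson noise. The 30 kb half-width is the megabase-scale spreading scaled
to the toy genome as described above.

*Expression counts.* Negative binomial with mean
`size_factor · μ_g · 2^logFC` and variance `μ + φμ²` (φ = 0.05; φ = 0
degenerates to Poisson), 3 replicates per condition, size factors uniform
on [0.8, 1.25], for the grid {uninduced, induced} × {vehicle, ATM
inhibitor}. The planted effect `logFC = −β · e_s · exp(−d/λ)` with β = 1.5
log2 units and λ = 10 kb applies only to induced-vehicle libraries; ATM
inhibition forces it to zero. The exponential decay form is an
identifiability choice — the data constrain only a monotone decay vanishing
by ~1 Mb — and is pluggable. Distance d is from the gene's nearest edge to
the nearest cut-site center, the same convention the analysis uses.

*Determinism.* Every output is a pure function of (config, seed); truth
tables round-trip losslessly through TSV + YAML.

## What the synthetic tests show — and what they do not

Passing recovery tests shows the chain is *correct* (it recovers planted
structure at realistic signal-to-noise) and *calibrated* (the null rejection
rate of the shift test is nominal when the effect is absent). They do not
demonstrate robustness to features the generator omits: mappability and
GC biases, fragment-size variation, chromatin-dependent background
clustering, resection at break ends, overlapping transcription units, or
dispersion trends across expression levels. Thresholds calibrated here
(log2 ratio ≥ 1, ≥ 3 origin reads) should be revisited on real libraries.

## Numerical conventions and problem sizes

Medians use midpoint interpolation. The exact rank-sum DP works on doubled
midranks (integers) with float64 subset counts; p-values are exact to
~1e-15 relative error. Peak/cluster operations sort by (chromosome,
midpoint, start) making all outputs order-independent. The test suite and
the acceptance script use a 10 Mb toy genome, 20 sites and 250 genes, with
100 effect replicates and 1,000 null replicates for the power/calibration
measurements; the full suite runs in under a minute on one CPU (plus ~20 s
for the replicate loops) and the acceptance script in ~15 s. Bin-mean
monotonicity in the distance-decay check is asserted up to the bins'
combined standard errors: adjacent cumulative bins differ by far less than
counting noise under a 10 kb decay length, so strict ordering is not a
property the generative model delivers at this sample size.

## Known limitations

The γH2AX rank score is a surrogate; no published formula exists. The exact
cutoff that produced the published 214-site list is unknown, so absolute
call counts are not comparable — ranking quality and detection of planted
truth are what the tests assert. DESeq2's rlog and CAGE tag clustering are
intentionally simplified (documented above). Genome-scale digestion is
supported and memory-flat, but the published hg19 site counts can only be
checked with the assembly FASTA present.
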