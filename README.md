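# dsbmap

Tools for mapping restriction-enzyme-induced DNA double-strand breaks (DSBs)
and quantifying how transcription is repressed around them.

The package targets the AsiSI / DIvA experimental design: a cell line carries
an inducible AsiSI restriction enzyme (recognition motif 5′-GCGATCGC-3′), so
break induction creates sequence-specific DSBs at a *subset* of the genomic
recognition sites. BLISS sequencing (breaks labelling *in situ* and
sequencing) marks break ends with read 5′ ends; γH2AX ChIP-seq marks the
megabase-scale phosphorylated-H2AX domains that spread around each break;
RNA-seq/CAGE-like count data measure the transcriptional consequences. The
pipeline identifies which recognition sites are actually cut, cross-validates
the two assays, and measures DSB-proximal transcriptional repression, its
distance dependence and its dependence on ATM kinase activity.

## What it computes

**Cut-site ranking (BLISS).** For each recognition site, the ±100 bp window is
quantified per library by the covered fraction *cf* (fraction of window bases
overlapped by at least one read) and the read coverage *rc* (per-base depth
contributed by window-originating reads; a read-count mode is also available).
The normalization chain is

    ln = rc / cf                 (local normalization)
    gn = ln / median(ln)         (global normalization over all sites)
    qn = quantile-normalized gn  (induced mapped rank-for-rank onto uninduced)

and sites are ranked by `log2[(qn_induced + ε) / (qn_uninduced + ε)]`; a site
is called cut when the log2 ratio passes a cutoff and enough induced reads
originate in the window.

**γH2AX domains.** Read counts in 250 bp windows are z-scored against a
trimmed background estimate; windows with z > 3 become peaks (adjacent
qualifying windows fuse), and peaks whose midpoints are within *n* bp merge
transitively into clusters. Sites are ranked by a log2 induced/uninduced RPM
enrichment over a ±5 kb flank that excludes the ±1 kb coverage dip at the
break. The intersection of BLISS calls with the top-K γH2AX sites gives a
gold-standard set.

**Expression impact.** Called sites are assigned to genes within ±2 kb;
per-gene log2 fold changes (size-factor-normalized, pseudocount, replicates
averaged on the log scale) are compared between cut genes and the rest with a
one-sided Wilcoxon rank-sum test (exact, tie-aware, for small problems);
metagene RPM profiles, distance-decay binning (cumulative 0.1/1/100/1000 kb
bins, a disjoint variant, and constant 200 kb bins), TSS expression classes
(k-means, Fisher enrichment of cut sites in the downregulated class) and a
binomial test of gene proximity complete the picture. An ATM-inhibitor
condition pair runs the same contrast with the repression abolished.

**Synthetic data.** A seeded generator produces a toy genome with planted
motifs and per-site cutting efficiencies, BLISS reads, γH2AX coverage, RNA
coverage and negative-binomial counts whose planted effect is
`logFC = −β · e_s · exp(−d/λ)`, plus a ground-truth table, so that every
stage can be tested for recovery of known structure.

## Worked example

```
$ dsbmap simulate --seed 7 --out demo
synthetic dataset written to demo

$ dsbmap digest --fasta demo/genome.fa --out demo/digest
20 motif occurrences (20 on reference chromosomes, 0 elsewhere); pooled density 2.000 per Mb

$ dsbmap bliss-rank --sites demo/digest.sites.bed \
    --induced demo/bliss_induced.bed --uninduced demo/bliss_uninduced.bed \
    --barcode AGTCGTAC --out demo/bliss
9 of 20 sites called

$ dsbmap h2ax-rank --sites demo/digest.sites.bed \
    --induced demo/h2ax_induced.bedgraph --uninduced demo/h2ax_uninduced.bedgraph \
    --topk 10 --out demo/h2ax
437 peaks, 117 clusters

$ dsbmap consensus --bliss demo/bliss.ranked.tsv --h2ax demo/h2ax.scores.tsv \
    --out demo/consensus.tsv
9 consensus sites

$ dsbmap expression --genes demo/genes.bed12 --counts demo/counts.tsv \
    --sites demo/bliss.called.bed --conditions demo/conditions.yaml --out demo/expr
9 cut genes vs 241 rest: one-sided Wilcoxon p = 2.76e-07
```

The toy genome plants 20 recognition sites of which 10 are cut (the ground
truth is in `demo/truth_sites.tsv`). BLISS ranking calls 9 — the tenth cut
site has the lowest planted efficiency — and no uncut site. All 9 calls also
rank in the γH2AX top 10, giving the 9-site consensus. Genes overlapping or
within 2 kb of a called site show fold changes shifted firmly below the rest
of the genes (p ≈ 3·10⁻⁷), the planted repression signal.

`dsbmap run --config pipeline.yaml` executes the whole chain from one
configuration file; see `docs/methods.md` for the model, parameters and
design choices.

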