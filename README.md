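# dpncall

Single-base calling of DNA N6-methyladenine (6mA) from
restriction-enzyme-digested sequencing libraries.

## The problem

6mA is a rare but functionally important DNA modification in eukaryotes.
A methylation-directed restriction enzyme (DpnI) cleaves duplex DNA at
adenine-methylated motifs — the canonical palindrome `GATC` and the
non-palindromic `CATC`/`GATG` pair — strongly preferring *fully*
methylated sites (6mA on both strands of the central ApT). If digested
genomic DNA is then randomly sheared, library-prepped and sequenced,
every cleavage event leaves a read 5′ end at a fixed offset inside the
motif, while sonication scatters 5′ ends uniformly. Calling 6mA sites
therefore reduces to asking, per candidate motif locus: are there more
read 5′ ends at the expected cut positions than random shearing can
explain?

`dpncall` implements that computational pipeline for people running such
assays (or evaluating them): motif scanning, strand-aware read-end
extraction from SAM/BAM, the binomial significance test, methylation-level
estimation, full/hemi classification from a dual-enzyme (DpnI + DpnII)
design, genomic annotation (promoter enrichment, TSS metagene
periodicity, sequence context), and a generative simulator of the whole
assay so every stage can be validated against known truth without any
external data.

## The statistical model

With n retained reads on a genome of size gs, a randomly sheared read's
5′ end hits any fixed position with probability 1/gs. A site aggregating
k expected end positions (k = 2 for a blunt double-strand cut) collects
ends as

    X ~ Binomial(n, k/gs),

and the evidence for cleavage at observed count x is the exact upper
tail P(X ≥ x). P-values are Bonferroni-corrected over the m tested motif
sites with significance threshold α = 0.01 (a Benjamini–Hochberg mode is
available), which keeps the expected fraction of falsely called sites
below 1%. The per-site methylation level is estimated as

    level = x / (x + spanning),

where `spanning` counts reads that cover the whole motif without
terminating at an expected cut position — molecules the enzyme left
intact. A significant site with spanning > x is classified *partial*
(only a minority of molecules carry the mark); otherwise *high*.

The dual-enzyme design adds DpnII, which cleaves only *unmethylated*
`GATC` and is blocked by hemi- or full methylation: sites cut by DpnI
and resistant to DpnII are **full**; DpnII-resistant but not DpnI-called
are **hemi**; DpnII-cut and not DpnI-called are **unmethylated**.

## Worked example

Simulate a 200 kb genome at 50× with 2% of motif sites fully methylated,
then call:

```sh
dpncall simulate --length 200000 --coverage 50 --methylated-fraction 0.02 \
        --seed 7 --out-dir demo
dpncall call --genome demo/genome.fa --alignments demo/reads.bed \
        --truth demo/truth.bed --out demo/calls.tsv
```

which logs

```
INFO dpncall: simulate: 2364 sites, 69720 reads (dpnI, seed=7) -> demo
INFO dpncall: call: n=69720 gs=200000 m=2364 cutoff=8 -> 36/2364 significant sites (demo/calls.tsv)
```

`n` is the retained read count, `m` the number of tested motif sites and
`cutoff=8` the smallest end count that reaches Bonferroni significance
under these conditions. The metadata sidecar `demo/calls.tsv.json`
reports `sensitivity: 1.0` and `fdr: 0.028` against the simulated truth,
and the calls table starts

```
chrom  start   end context  x  spanning        pvalue  significant  methylation_level status strand
 sim1   2729  2733    GATG 94         6 8.2e-162             True               0.94   high      -
 sim1  15008 15012    GATC 94         6 8.2e-162             True               0.94   high      +
```

— at a fully methylated site nearly every molecule was cut (x = 94 cut
ends vs 6 spanning reads, level 0.94 ≈ the simulated digestion
efficiency 0.95). `dpncall annotate` then produces region fractions,
the TSS metagene profile with its dominant period, the tetramer-context
breakdown and the flanking-composition matrix; `dpncall integrate`
labels full/hemi sites from a DpnI + DpnII pair of call sets.

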