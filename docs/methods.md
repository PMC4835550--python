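# Methods

## Assay model

A methylation-directed restriction enzyme (DpnI) cleaves duplex DNA at
6mA-bearing recognition motifs. After digestion, DNA is randomly sheared
(sonication, ~300 bp), library-prepped and sequenced; each fragment end
yields a read whose 5′ end marks the fragment boundary. Enzymatic
cleavage concentrates 5′ ends at fixed offsets inside the motif;
shearing scatters them uniformly. The pipeline tests each candidate
motif locus for an excess of 5′ ends at its expected cut positions.

Coordinates are 0-based half-open throughout; SAM's and GFF3's 1-based
conventions are converted at the I/O boundary, and BED output is
0-based.

## Motifs and cut register

Default motif set: `GATC` (palindromic, reported once per locus) and
`CATC`, whose reverse complement `GATG` is matched as a minus-strand
occurrence. Both default to a blunt double-strand cut between the A and
T (GA^TC, CA^TC), the known register of DpnI on GATC; base-level cut
positions inside CATC/GATG are not established, so the register is
configurable per motif. A blunt cut at offset c inside an occurrence
[s, s+L) on '+' puts expected read 5′ ends at (s+c, '+') and
(s+c−1, '−'); a minus-strand occurrence mirrors the offsets. DpnII
(used in the complementary library) actually leaves a 4-nt 5′ overhang
at ^GATC; since end repair blunts overhangs and only cut/uncut status
matters downstream, it is modeled as a blunt cut at the motif start.

Matching is exact over A/C/G/T; motifs never match through N, and sites
overlapping N are absent by construction (counted in a log summary).
Overlapping occurrences are all reported and tested independently.

## Read ends and per-site evidence

A retained alignment contributes exactly one 5′ end: its leftmost
reference position on '+', rightmost on '−'. Unmapped, secondary,
supplementary and duplicate records are dropped, as are records below
mapping quality 10 (configurable) and reads soft-clipped at the 5′ end
of interest (clipping obscures the true fragment end; a flag retains
them). Per site, the statistic x sums end counts over the expected end
positions, optionally widened by a ±w jitter window (default w = 0;
w = 1 absorbs end-repair nibbling). The spanning count requires a read
to cover the *full* motif interval — not merely the cut position — so
that reads stopping inside the motif cannot inflate the uncut
denominator; reads terminating exactly at an expected end position are
excluded from spanning even when a boundary cut register would let them
cover the motif.

## Significance, level, classification

Null: X ~ Binomial(n, k/gs) with n = retained reads, gs = genome size,
k = number of aggregated end positions (2 for a blunt cut, scaled up by
the jitter window). The per-locus background 1/gs is multiplied by k so
the null matches the statistic actually summed. P-value: exact upper
tail P(X ≥ x) via the regularized incomplete beta function, stable for
n up to 10^8 and p down to 10^−10 (verified against an
arbitrary-precision oracle to 10^−6 relative error).

Multiple testing: Bonferroni over the m tested motif sites at α = 0.01,
with strict inequality (p·m < α), so ties at the threshold are not
called; a Benjamini–Hochberg mode at q = α is provided and recorded in
the run metadata. m defaults to the number of tested sites and can be
overridden. The minimum-read-end cutoff x* — the smallest count that
reaches significance — is derived by binary search on the monotone tail
and logged with every run.

Methylation level = x/(x+spanning), undefined (NaN) with no evidence at
all; such zero-coverage sites are still reported (status unmethylated,
no-data flag) so the output audits the complete motif universe.
Classification: *partial* iff significant and spanning > x, *high* iff
significant otherwise, else *unmethylated*. Dual-enzyme integration
over GATC sites: full = DpnI-called ∧ DpnII-resistant; hemi =
DpnII-resistant only (sites seen only in the resistant set are hemi);
unmethylated = DpnII-cut, not DpnI-called; discordant = DpnI-called yet
DpnII-cut (logged).

## Annotation

Promoter = TSS ± 1 kb (configurable); promoter takes precedence over
genic so the promoter/genic/intergenic labels partition the calls.
Metagene: each site is assigned to its nearest same-contig TSS (exact
ties to the lower coordinate), distances oriented by gene strand,
binned at 10 bp over ±2 kb by default (window and bin are choices, not
assay constants); density is per bp per TSS. Periodicity: argmax over
lags of the normalized autocorrelation of the mean-subtracted profile,
searched between 50 and 500 bp (nucleosome-scale); a zero-variance
profile returns undefined. Context breakdown pools CATC with GATG (two
readings of one duplex motif). The composition matrix reports per-offset
base frequencies around the methylated A, oriented 5′→3′ on the A's
strand, skipping windows truncated by contig edges or containing N; it
is the numeric input of a sequence logo.

## Simulator

The generator's defaults are the study conditions the pipeline is
validated under: 1 Mb i.i.d. genome at GC 0.5; 2% of motif sites
methylated, all fully (full_fraction 1.0); mean fragment length 300 bp;
coverage 50 molecules; molecule-level methylation fraction q = 1
(a 'uniform' mode draws q ∈ [0.01, 0.10] per site to emulate genomes
where most sites are methylated in a small fraction of cells).
Digestion-time efficiency presets, per (motif, status):

| preset    | GATC full | GATC hemi | CATC full | CATC hemi |
|-----------|-----------|-----------|-----------|-----------|
| overnight | 0.95      | 0.3       | 0.9       | 0.0       |
| 30min     | 0.95      | 0.05      | 0.2       | 0.0       |

The qualitative ordering (full ≫ hemi; hemi CATC ≈ 0; the enzyme is
strongly full-specific only in a limited incubation) is what the assay
establishes; the numeric values are conventions and all
config-exposed. Dual-enzyme classification uses the 30-minute preset,
because discriminating full from hemi requires the time window in which
hemi GATC is barely cleaved — with overnight hemi efficiency (0.3) a
50× library makes many hemi sites statistically significant in the
DpnI channel, and no caller could label them hemi. DpnII efficiency:
0.95 at unmethylated GATC, 0 when the molecule carries 6mA.

Per molecule (one genome copy), each site is cut with probability
q·efficiency (DpnI) or (1−q)·efficiency (DpnII); shear breakpoints
follow a Poisson process at rate 1/mean_fragment_length (the simplest
process consistent with a stated mean and no stated distribution);
enzymatic cuts are applied before shearing, matching the protocol
order. Each fragment emits one read per strand. Reads default to whole
fragments (read_length = None): this keeps cut-end counts (2 per cut
molecule) and spanning counts (2 per intact molecule whose covering
fragment spans the motif) on the same per-molecule scale, so
x/(x+spanning) is a calibrated estimator of q·efficiency. With short
fixed-length reads the spanning count would undercount intact molecules
and the level estimate would be biased upward — a real-data caveat
documented below. No sequencing-error, PCR-bias or diploidy model;
alignment is assumed perfect (mapping is upstream of this tool).

What the simulator does not emulate: non-uniform genome composition
and mappability, chromatin-dependent shearing bias, end-repair
artifacts beyond the jitter option, PCR duplicates, and finite read
length (see above). Passing the recovery tests therefore demonstrates
the statistical machinery is correct under the model's assumptions,
not that real libraries are free of these biases.

## Numerical and degenerate-input choices

- Strict inequality at the Bonferroni threshold (ties not called).
- Upper-tail p-values computed vectorized via `scipy.stats.binom.sf`.
- Empty evidence lists return empty call sets; an empty alignment file
  yields an all-no-data audit, not an error.
- An unreachable significance level (even x = n not significant) raises
  rather than returning a sentinel cutoff.
- Metagene ties between equidistant TSSs break deterministically to the
  lower coordinate; same-seed runs are byte-identical end to end.
- Composition-matrix rows renormalize over used sites only; edge and
  N-containing windows are counted, not silently dropped.

## Problem sizes used in validation

The bundled validation suite runs desk-scale simulations: 1 Mb genomes
for null calibration (200,000 read ends) and parameter recovery (50×),
500 kb for dual-enzyme classification, 500 synthetic TSSs for
periodicity recovery, and 10 × 100 kb genomes for the motif-scan
oracle. These sizes give tight empirical bounds (thousands of tested
sites per run) while keeping the whole suite fast; all scale linearly
if rerun larger.

## Known limitations

- Exact cut registers inside CATC/GATG are assumed, not measured;
  configurable if refined data appear.
- The caller treats strands jointly (a blunt cut couples them); no
  per-strand calling.
- m (test family) defaults to tested motif sites, not all genomic
  positions; override available.
- Hemi-methylated GATC sites partially cleaved by DpnI in long
  incubations can surface as "discordant" in the integration; the
  30-minute preset minimizes but does not eliminate this.
- Methylation-level estimates from real short-read libraries inherit a
  cut-vs-spanning scale mismatch (see Simulator); levels are best
  interpreted comparatively, and the partial/high distinction is robust
  to it.
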