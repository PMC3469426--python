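# Methods

This note documents the models behind each suvrkit component, the
parameters that matter, and what the synthetic data do and do not emulate.
Coordinates are 0-based half-open internally; GFF3 is written 1-based
inclusive, BED 0-based half-open, and cytosine reports carry 1-based
positions.

## Motif model and exact p-values

A binding site is a position weight matrix (PWM): per-position base
frequencies `f[i][b]` over A,C,G,T, scored in log-odds bits against a
background `b[x]` (uniform 0.25 by default). `build_pwm` estimates
`f[i][b] = (count + pseudocount) / (n + 4*pseudocount)`; with no
pseudocount, zero frequencies are legal and are floored at 2⁻³⁰ for
scoring so log-odds stay finite (a window using such a base can never pass
a sensible threshold).

Occurrence p-values are exact, not sampled: per-position scores are rounded
to 10⁻³ bits and the distribution of their sum under the background is
built by position-wise convolution. The p-value of a score is the tail mass
at or above it; the discretization error is at most one 10⁻³-bit bin per
position, and the test suite brackets every DP p-value between enumeration
tails at score ± w·10⁻³ over all 4^w words (w ≤ 8). A query above the
attainable maximum returns the mass of the best word rather than 0, so
p ≥ 4⁻ʷ under a uniform background. `pvalue_threshold_score` inverts the
tail; scanning applies it per strand, scoring the minus strand with the
reverse-complemented matrix and reporting hits at their forward-strand
start. Both strand hits of a palindromic motif at one start are reported
separately, matching standard scanner behavior.

## ZOOPS EM discovery

`discover_motif` fits a zero-or-one-occurrence-per-sequence mixture: each
read carries a site at one of its windows (either strand, prior γ spread
uniformly over windows) or no site (1−γ). The E-step computes per-window
posteriors from PWM-vs-background likelihood ratios; the M-step
re-estimates frequencies (with a Dirichlet-style pseudocount, default
0.25 per cell) and γ. Initialization uses the most frequent
strand-collapsed k-mers plus random site draws (`restarts`); the
highest-likelihood fit wins. The tracked objective is the data
log-likelihood relative to the all-background model; because the
pseudocount is a MAP prior, the data likelihood can dip marginally at a
fixed point, in which case the fit reverts to the previous state, so the
reported history is non-decreasing. When `width` is a range, the width with
the largest penalized log-likelihood ratio wins; the penalty defaults to
1.5·ln(n_reads) per column, a BIC-style charge for the three free
parameters of a column. A fit whose total information content falls below
`ic_floor` (default 6 bits) is flagged `no_motif`; on 200 uniform random
50-mers the spurious optimum sits near 3–4 bits, well below planted-motif
fits (~15 bits), so the floor separates the two regimes with a wide margin.

## SELEX simulation

Pools are either oligos with a 15 bp random core between fixed flanks or
~100 bp genomic fragments (random strand, uniform start). Each cycle
resamples `reads_per_cycle` fragments with replacement, weighted by

    retention = carryover + (1 − carryover) · logistic(stringency · (s − m))

where `s` is the fragment's best-window log-odds score and the midpoint `m`
is the score at occurrence p ≤ 10⁻⁴ (near-perfect sites). A pure logistic
centred at the scan threshold cannot reproduce the observed
one-cycle-flat / nine-cycle-enriched contrast at toy pool sizes: perfect
sites and 1–2-mismatch near-matches both saturate the logistic, and moving
the midpoint to the maximum makes a single cycle fixate the pool. The
`carryover` term (default 0.3) models nonspecific retention — incomplete
washing — so one cycle barely shifts pool composition while nine cycles
compound into exponential enrichment of perfect sites. Both knobs are
exposed; `stringency = 0` is the affinity-blind control. A fragment's score
never changes, so the input pool is scored once and indices are tracked
through the resampling.

## ChIP-chip region calling

Probe normalization is log₂(IP/input) followed by per-array centering to
mean zero. The genome is tiled into 500 bp bins every 250 bp; a bin's score
is the mean over probes whose midpoint falls inside it (midpoint
assignment is the simplest unbiased rule for overlapping tiles), and
probe-free bins are missing, never zero. The difference track is
`mutant − wildtype` per bin — both scores are already log₂ quantities, so
this equals the log₂ of the intensity-ratio quotient — and is Z-transformed
over all non-missing bins genome-wide (not per chromosome) with the
population standard deviation; at genome-scale bin counts the
sample-vs-population distinction is negligible. Bins with Z < −3 are
flagged, flagged bins within 2.5 kb are merged (missing bins do not extend
a run, though the merge gap may bridge them), and a region must contain at
least `min_bins = 3` flagged bins. The support filter is what reconciles
the per-bin false-flag rate — by construction ≈ Φ(−3) ≈ 0.00135
genome-wide on pure noise — with a clean region-level null: isolated
sub-threshold bins occur by the dozen on any genome-sized track, but three
co-occurring within one merge gap is rare (expected ≪ 1 per genome),
while genuine multi-kilobase depletions span ~10–20 bins. All three
thresholds are parameters.

A practical sizing note: the Z denominator includes the planted (or real)
depleted patches themselves, so if depletion covers a large fraction of
bins it inflates the standard deviation and pushes patch Z-scores back
above the cutoff. The simulators keep depletion below ~6% of bins; on real
arrays the equivalent concern is a genotype with genome-scale loss of
signal.

## Metaplots

A feature's profile is `flank_bins` fixed-width upstream bins, `body_bins`
linearly rescaled body bins, and `flank_bins` downstream bins;
minus-strand features are reversed so bin 0 is always 5′-most. Per-bin
values are missing-aware means over features; features shorter than
`body_bins` bp are skipped with a warning. Methylation metaplots pool read
counts within each (feature, bin) before dividing, then average the
resulting levels across features, so deep sites dominate within a bin but
every feature contributes equally.

## Methylation

Contexts are classified strand-aware from the reference: a cytosine is CG
if the next base (3′ on its own strand) is G, CHG if the base after that
is G, else CHH; cytosines too close to a chromosome end to decide are
`incomplete` and excluded from summaries. Minus-strand cytosines are
reported at their own coordinate (the forward-strand G position). Levels
are weighted — Σ meth / Σ total — rather than means of per-site fractions,
which makes bulk and windowed summaries robust to depth variation. Clone
analysis reads pre-aligned converted sequences against the reference
(C→T on plus-strand clones, G→A on minus-strand clones) and reports
per-site percent methylation; a clone base that is neither the reference
base nor a conversion product excludes that clone at that site.

## Differential expression

The design deliberately has no replicates: each gene is tested with a 2×2
Fisher exact table of (gene count, library − gene count) in the two
samples, the standard single-library construction. The two-sided p sums
hypergeometric probabilities of all tables with the observed margins whose
probability does not exceed the observed table's (with a 1+10⁻⁷ relative
gate against floating-point ties; values that underflow double precision
are floored at the smallest positive double). P-values are BH-adjusted
across all tested genes. A gene is called up-regulated when its RPKM log₂
ratio exceeds `min_log2_fold` and its adjusted q is below `alpha` (raw-p
mode available by flag). Two readings of the published fold cutoff exist —
"over 4 fold" and a literal "log₂ ratio > 4" (16-fold); they are
inconsistent, so both are implemented and neither is silently reconciled:
the default is `min_log2_fold = 2`, the 16-fold reading is `= 4`. The q
criterion is used because the correction is named in the same sentence as
the cutoff. A 0.5-RPKM pseudo-term keeps zero-count genes finite.

Fisher significance under negative-binomial noise is anti-conservative in
principle (the test assumes Poisson-like sampling), which is why the null
control matters: on fully null matrices at dispersion 0.05 the full rule
calls ~0.03% of genes, dominated by the fold cutoff rather than the test.

## Synthetic data: what it emulates and what it does not

The default genome is 2 chromosomes × 200 kb with a central pericentromere
(25% of each chromosome), 100 genes of 0.8–2.5 kb in the arms, and 60 TEs
of 0.3–1.5 kb placed 85% inside pericentromeres, all separated by ≥100 bp;
placement samples uniformly from the remaining free space, so it is exact
rather than rejection-based and fails only when space truly runs out. GC
content defaults to 0.36 (the A. thaliana genome average). Gene baseline
expression is log-normal (median 50, σ = 1).

Planted layers: one `TACTAGTA` copy in the 1 kb upstream window of 40% of
genes (sense orientation; the palindrome makes strand moot); H3K9me2
depletion patches of 3 kb at −2.0 log₂ units, 5 shared between genotypes
plus 3 exclusive each, placed in the arms on the tiling grid ≥10 kb apart;
methylation levels per compartment and context (pericentromere/TE: CG
0.85, CHG 0.45, CHH 0.08; arms: 0.15/0.03/0.015; methylation-independent
patches: ≤0.02 in every genotype — the negative control for
DNA-methylation-independent silencing), binomial at fixed depth; RNA-seq
counts gamma-Poisson with variance m + d·m² (d = 0.05 by default, Poisson
at d = 0), with 16-fold up-regulation planted identically across genotypes
on genes drawn from the lowest-expressed third. The low-expression
targeting mirrors the biology (the co-regulated genes are silenced in wild
type) and is also what keeps a 100-gene closed library usable: planting
large folds on high-expression genes shifts the library composition enough
to halve every apparent ratio.

Not emulated: sequencing errors and quality scores, alignment ambiguity
(mapping is exact-match on toy genomes), array spatial artifacts and dye
bias, bisulfite conversion failure, replicate structure, and real genome
repeat content. Passing recovery tests therefore demonstrates that the
*calling logic* is correct under its stated noise models, not that the
pipeline is robust to real-data artifacts upstream of it.

## Pipeline and reproducibility

One global seed fans out to per-stage seeds by fixed offsets
(`seed·1009 + k mod 2³¹`), so stages can be rerun in isolation. No output
embeds a timestamp; rerunning a config reproduces every file byte for
byte, and each file's `.prov.json` sidecar records its parameters, seed
and input digests. Demo-scale problem sizes (200 kb chromosomes, 4,000-
fragment SELEX pools, 300 reads for EM, 300k-read libraries) were chosen
so the full pipeline completes in seconds while every recovery statistic
retains a comfortable margin; all are config keys.

The acceptance script reports the null DE control at the study's stated
scale (5,000 genes, 10⁶-read libraries, 20 replicate simulations) rather
than the demo scale.

## Known limitations

* The exact p-value DP assumes position independence (a standard PWM
  assumption); dinucleotide composition of real genomes makes effective
  background hit rates higher than the uniform-background p suggests.
* "Contains the motif" statistics in the report use literal consensus-word
  matches; at p ≤ 0.001 the near-match density (~1 hit/kb/strand) saturates
  any ±2 kb window on a toy genome, and would on a real one too.
* The epistasis descriptor is a ratio of median shifts and is undefined
  when the single mutant does not differ from wild type.
* `interval_overlap_venn` counts from each set's perspective separately;
  merged-region counts differ between sets, so the two shared counts need
  not be equal.
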