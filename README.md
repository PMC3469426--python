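# suvrkit

A toolkit for studying how a zinc-finger, SET-domain histone
methyltransferase (the *Arabidopsis* SUVR5 type) targets H3K9me2 silencing
to specific promoters independently of DNA methylation. The protein binds a
palindromic DNA octamer (`TACTAGTA`) through its zinc fingers; suvrkit
implements the complete computational side of that analysis and exercises
it end-to-end on synthetic genomes carrying planted ground truth:

* **Binding-motif discovery and scanning** — SELEX read pools, strand-collapsed
  k-mer enrichment, ZOOPS EM motif discovery, and PWM scanning with *exact*
  occurrence p-values computed by dynamic programming over the discretized
  log-odds score distribution (p(s) = P(Σᵢ log₂ fᵢ(xᵢ)/bᵢ ≥ s) for a
  background w-mer).
* **ChIP-chip differential region calling** — per-probe log₂(IP/input),
  per-array centering, 500 bp / 250 bp overlapping tiles, a genome-wide
  Z-transform of the mutant − wild-type difference track, a Z < −3 cutoff,
  and merging of flagged bins within 2.5 kb.
* **Bisulfite methylation summaries** — strand-aware CG/CHG/CHH context
  classification (H = A, C or T), weighted levels Σmeth/Σtotal, chromosome
  tracks, metaplots, and single-locus clone analysis.
* **Differential expression without replicates** — RPKM = 10⁹·c/(N·L),
  per-gene two-sided Fisher exact tests of gene-vs-rest-of-library counts,
  Benjamini–Hochberg correction, and a fold + q calling rule.
* **Interval integration** — promoter windows, exact-match read mapping,
  Venn overlaps of called region sets, motif-presence fractions, and
  gene-set cross-references, including the epistasis summary for mutants
  acting in one pathway.
* **Synthetic data with planted truth** — every layer (genome, SELEX pools,
  probe arrays, methylomes, counts) is generated with a known answer key, so
  every caller above is tested by recovery.

## Worked example

Run the demo pipeline (simulates all layers on a 2 × 200 kb genome, then
runs motif discovery, region calling, methylation summaries, DE and
integration; ~10 s on one core):

```bash
suvrkit run --config examples/demo.yaml
```

The summary it prints (also written to `suvrkit_demo/summary.json`):

```json
{
  "motif": {
    "discovered_consensus": "TACTAGTA",
    "palindromic": true,
    "selex_motif_fraction_by_cycle": [0.09, 0.20, 0.40, 0.63, 0.82, 0.92, 0.97, 0.99, 1.00, 1.00]
  },
  "chip": {
    "n_regions": {"suvr5": 8, "kyp_suvh5_suvh6": 8},
    "venn": {"a_only": 3, "shared_a": 5, "pct_suvr5_specific": 37.5}
  },
  "expression": {
    "n_called": {"suvr5": 28, "ldl1_ldl2": 20, "suvr5_ldl1_ldl2": 20},
    "n_shared_called": 19,
    "epistasis_descriptor": 1.14
  },
  "truth": {"n_planted_motif_sites": 40, "n_planted_patches": 11,
            "n_planted_de": {"suvr5": 30, "ldl1_ldl2": 20, "suvr5_ldl1_ldl2": 20}}
}
```

Reading it against the planted truth: EM on the cycle-9 SELEX pool recovers
the planted palindrome exactly; the site-bearing read fraction climbs from
9% to ~100% across nine selection cycles (the one-cycle pool is the flat
control); the region caller finds all 8 planted H3K9me2-depleted patches
per genotype and the Venn split (3 exclusive / 5 shared) matches the
planted design; the DE caller recovers 28 of 30 planted 16-fold genes in
*suvr5* and 19 of the 20 genes planted jointly across genotypes, with an
epistasis descriptor near 1 — the combined mutant adds nothing beyond the
single mutant, as designed.

Each emitted file carries a `.prov.json` sidecar (parameters, seed, input
digests); rerunning the same config reproduces every file byte for byte.

The same operations are available as library functions
(`suvrkit.motif.discover_motif`, `suvrkit.chip.call_decreased_regions`,
`suvrkit.expression.call_differential_genes`, ...) and as focused CLI
subcommands (`suvrkit motif scan`, `suvrkit chip call-regions`,
`suvrkit de call`, `suvrkit integrate venn`, ...).

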