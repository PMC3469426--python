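"""Interval-level synthesis of the binding, chromatin and expression layers.

Promoter windows, exact-match read mapping on toy genomes, Venn overlap of
called region sets, motif-presence fractions around features, and
promoter-signal gene sets. All intervals are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from . import chip
from .motif import reverse_complement


def promoter_intervals(genes: pd.DataFrame, upstream: int,
                       chrom_sizes: Mapping[str, int] | None = None) -> pd.DataFrame:
    """Strand-aware windows of ``upstream`` bp ending at each TSS.

    Plus-strand gene [s, e): promoter [s-upstream, s); minus-strand gene:
    promoter [e, e+upstream). Windows are clipped at chromosome bounds.
    """
    if upstream <= 0:
        raise ValueError("upstream must be > 0")
    rows = []
    for _, g in genes.iterrows():
        if g["strand"] == "+":
            start, end = int(g["start"]) - upstream, int(g["start"])
        else:
            start, end = int(g["end"]), int(g["end"]) + upstream
        start = max(0, start)
        if chrom_sizes is not None:
            end = min(end, chrom_sizes[g["chrom"]])
        if end > start:
            rows.append((g["chrom"], start, end, g["strand"], g["id"]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "gene_id"])


def _count_occurrences(haystack: str, needle: str) -> int:
    count = start = 0
    while True:
        idx = haystack.find(needle, start)
        if idx < 0:
            return count
        count += 1
        start = idx + 1


def map_reads_exact(reads: Mapping[str, str] | Sequence[str],
                    chromosomes: Mapping[str, str]
                    ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Map reads by exact substring search on both strands.

    Reads with exactly one genomic occurrence become intervals; multi-mappers
    and non-mappers are discarded and counted. Duplicate read sequences each
    contribute their own interval (pool multiplicity is signal).
    """
    if not isinstance(reads, Mapping):
        reads = {f"read{i}": r for i, r in enumerate(reads)}
    cache: dict[str, tuple | None] = {}
    rows = []
    stats = {"mapped": 0, "multi": 0, "unmapped": 0}
    for name, read in reads.items():
        read = read.upper()
        if read not in cache:
            hits = []
            rc = reverse_complement(read)
            for chrom, seq in chromosomes.items():
                n_fwd = _count_occurrences(seq, read)
                n_rev = _count_occurrences(seq, rc) if rc != read else 0
                if n_fwd + n_rev > 1:
                    hits = [None, None]
                    break
                if n_fwd == 1:
                    hits.append((chrom, seq.find(read), "+"))
                if n_rev == 1:
                    hits.append((chrom, seq.find(rc), "-"))
            cache[read] = hits[0] if len(hits) == 1 else ("multi" if hits else None)
        hit = cache[read]
        if hit is None:
            stats["unmapped"] += 1
        elif hit == "multi":
            stats["multi"] += 1
        else:
            chrom, start, strand = hit
            rows.append((chrom, start, start + len(read), strand, name))
            stats["mapped"] += 1
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "name"])
    return df.sort_values(["chrom", "start"]).reset_index(drop=True), stats


def merge_interval_set(df: pd.DataFrame, gap: int = 0) -> pd.DataFrame:
    """Merge overlapping/nearby intervals of a set, per chromosome."""
    rows = []
    for chrom, cdf in df.groupby("chrom", sort=True):
        ivals = sorted(zip(cdf["start"].astype(int), cdf["end"].astype(int)))
        for start, end in chip.merge_regions(ivals, gap):
            rows.append((chrom, start, end))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


@dataclass
class VennResult:
    a_total: int
    b_total: int
    shared_a: int      # merged A regions overlapping B (A-perspective count)
    shared_b: int
    a_only: int
    b_only: int
    a_shared_index: list[int]
    b_shared_index: list[int]


def interval_overlap_venn(set_a: pd.DataFrame, set_b: pd.DataFrame,
                          min_overlap: int = 1) -> VennResult:
    """Two-set overlap with counts kept from each set's own perspective.

    Both sets are merged internally first. A merged region of A is shared
    iff it overlaps at least ``min_overlap`` bp with some region of B.
    Because merged-region counts differ between sets, A- and B-perspective
    shared counts are both reported; a_only + shared_a = |merged A| always.
    """
    a = merge_interval_set(set_a)
    b = merge_interval_set(set_b)

    def shared(query: pd.DataFrame, subject: pd.DataFrame) -> list[int]:
        trees: dict[str, IntervalTree] = {}
        for _, r in subject.iterrows():
            trees.setdefault(r["chrom"], IntervalTree()).addi(r["start"], r["end"])
        out = []
        for i, r in query.iterrows():
            tree = trees.get(r["chrom"])
            if tree is None:
                continue
            for iv in tree.overlap(r["start"], r["end"]):
                if min(iv.end, r["end"]) - max(iv.begin, r["start"]) >= min_overlap:
                    out.append(i)
                    break
        return out

    sa = shared(a, b)
    sb = shared(b, a)
    return VennResult(len(a), len(b), len(sa), len(sb),
                      len(a) - len(sa), len(b) - len(sb), sa, sb)


def fraction_features_with_motif(features: pd.DataFrame, hits: pd.DataFrame,
                                 flank: int = 2000) -> tuple[float, pd.Series]:
    """Fraction of features with >= 1 motif hit start within [start-flank, end+flank)."""
    if len(features) == 0:
        raise ValueError("features must be nonempty")
    trees: dict[str, IntervalTree] = {}
    for _, h in hits.iterrows():
        trees.setdefault(h["chrom"], IntervalTree()).addi(h["start"], h["start"] + 1)
    flags = []
    for _, f in features.iterrows():
        tree = trees.get(f["chrom"])
        lo = max(0, int(f["start"]) - flank)
        hi = int(f["end"]) + flank
        flags.append(bool(tree is not None and tree.overlap(lo, hi)))
    flags = pd.Series(flags, index=features.index, name="has_motif")
    return float(flags.mean()), flags


def genes_with_upstream_signal(genes: pd.DataFrame, signal: pd.DataFrame,
                               upstream: int, chrom_sizes: Mapping[str, int] | None = None,
                               min_intervals: int = 1) -> set[str]:
    """Gene ids whose upstream promoter window overlaps >= min_intervals signal intervals."""
    promoters = promoter_intervals(genes, upstream, chrom_sizes)
    trees: dict[str, IntervalTree] = {}
    for _, s in signal.iterrows():
        trees.setdefault(s["chrom"], IntervalTree()).addi(s["start"], s["end"])
    out = set()
    for _, p in promoters.iterrows():
        tree = trees.get(p["chrom"])
        if tree is not None and len(tree.overlap(p["start"], p["end"])) >= min_intervals:
            out.add(p["gene_id"])
    return out
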