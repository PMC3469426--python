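"""Context-resolved bisulfite methylation summaries.

Plant cytosine methylation is reported in three sequence contexts — CG, CHG
and CHH (H = A, C or T) — classified strand-aware against the reference.
Levels are "weighted": sum of methylated read counts over sum of total read
counts, which is robust to per-site depth variation. Minus-strand cytosines
are reported at their own coordinate (the G position on the forward
reference).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import chip
from .motif import encode

CONTEXTS = ("CG", "CHG", "CHH")


@dataclass
class Methylome:
    """Sorted per-cytosine calls for one sample/genotype."""

    calls: pd.DataFrame  # chrom, pos (0-based), strand, context, meth_count, total_count

    def __post_init__(self) -> None:
        df = self.calls
        if (df["meth_count"] > df["total_count"]).any():
            raise ValueError("meth_count must not exceed total_count")
        if df.duplicated(["chrom", "pos", "strand"]).any():
            raise ValueError("duplicate (chrom, pos, strand) keys")
        cols = ["chrom", "pos", "strand", "context", "meth_count", "total_count"]
        self.calls = (df.loc[:, cols].sort_values(["chrom", "pos", "strand"])
                      .reset_index(drop=True))

    def to_tsv(self, path: str | Path) -> None:
        from . import io as _io
        _io.write_cytosine_report(path, self.calls)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Methylome":
        from . import io as _io
        return cls(_io.read_cytosine_report(path))


def classify_contexts(chromosomes: Mapping[str, str]) -> pd.DataFrame:
    """Classify every cytosine on both strands of the reference.

    Plus strand: a C at i is CG if base i+1 is G, CHG if base i+2 is G,
    else CHH. Minus strand: a G at i is a reverse-strand C; reading 3'->5'
    on the forward sequence, it is CG if base i-1 is C, CHG if base i-2 is
    C, else CHH. Cytosines without enough lookahead near a chromosome end
    get context 'incomplete' and are excluded from summaries.
    """
    frames = []
    for chrom, seq in chromosomes.items():
        codes = encode(seq)
        n = len(codes)
        # padded lookahead/lookbehind: -9 marks "off the end"
        padded = np.concatenate([[-9, -9], codes, [-9, -9]])
        for strand, c_code, g_code, step in (("+", 1, 2, 1), ("-", 2, 1, -1)):
            pos = np.nonzero(codes == c_code)[0]
            nxt1 = padded[pos + 2 + step]
            nxt2 = padded[pos + 2 + 2 * step]
            ctx = np.select(
                [nxt1 == g_code, (nxt1 == -9) | ((nxt2 == -9) & (nxt2 != g_code)),
                 nxt2 == g_code],
                ["CG", "incomplete", "CHG"], default="CHH")
            frames.append(pd.DataFrame({"chrom": chrom, "pos": pos,
                                        "strand": strand, "context": ctx}))
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "pos", "strand", "context"])
    return df.sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)


def weighted_level(methylome: Methylome, context: str | None = None,
                   interval: tuple[str, int, int] | None = None) -> float | None:
    """Sum(meth)/sum(total) over calls of one context in an interval.

    Returns None (a missing value, not 0) when no calls of the context
    overlap the interval.
    """
    df = methylome.calls
    if context is not None:
        df = df[df["context"] == context]
    if interval is not None:
        chrom, start, end = interval
        df = df[(df["chrom"] == chrom) & (df["pos"] >= start) & (df["pos"] < end)]
    total = int(df["total_count"].sum())
    if total == 0:
        return None
    return float(df["meth_count"].sum() / total)


def windowed_track(methylome: Methylome, chrom_sizes: Mapping[str, int],
                   window: int = 50_000, step: int = 10_000) -> pd.DataFrame:
    """Per-window weighted levels for each context (chromosome views).

    Windows lacking calls of a context get NaN, never 0.
    """
    if window < step:
        raise ValueError("require window >= step")
    rows = []
    df = methylome.calls
    for chrom, length in chrom_sizes.items():
        cdf = df[df["chrom"] == chrom]
        per_ctx = {}
        for ctx in CONTEXTS:
            xdf = cdf[cdf["context"] == ctx].sort_values("pos")
            pos = xdf["pos"].to_numpy()
            cm = np.concatenate([[0], np.cumsum(xdf["meth_count"].to_numpy())])
            ct = np.concatenate([[0], np.cumsum(xdf["total_count"].to_numpy())])
            per_ctx[ctx] = (pos, cm, ct)
        start = 0
        while start < length:
            end = min(start + window, length)
            row: dict = {"chrom": chrom, "start": start, "end": end}
            for ctx in CONTEXTS:
                pos, cm, ct = per_ctx[ctx]
                lo = int(np.searchsorted(pos, start, "left"))
                hi = int(np.searchsorted(pos, end, "left"))
                tot = ct[hi] - ct[lo]
                row[ctx] = (cm[hi] - cm[lo]) / tot if tot > 0 else np.nan
            rows.append(row)
            start += step
    return pd.DataFrame(rows)


def meth_metaprofile(methylome: Methylome, features: pd.DataFrame, flank: int = 2000,
                     body_bins: int = 40, flank_bins: int = 20
                     ) -> dict[str, pd.DataFrame]:
    """Per-context metaplots over stranded features.

    Read counts are pooled within each (feature, layout bin) before dividing,
    then the per-bin weighted levels are averaged across features with
    missing-aware means, mirroring the signal metaprofile layout.
    """
    if len(features) == 0:
        raise ValueError("features must be nonempty")
    df = methylome.calls
    n_layout = body_bins + 2 * flank_bins
    out: dict[str, pd.DataFrame] = {}
    for ctx in CONTEXTS:
        xdf = df[df["context"] == ctx]
        per_chrom = {}
        for chrom, cdf in xdf.groupby("chrom", sort=False):
            cdf = cdf.sort_values("pos")
            per_chrom[chrom] = (
                cdf["pos"].to_numpy(),
                np.concatenate([[0], np.cumsum(cdf["meth_count"].to_numpy())]),
                np.concatenate([[0], np.cumsum(cdf["total_count"].to_numpy())]),
            )
        sums = np.zeros(n_layout)
        counts = np.zeros(n_layout, dtype=int)
        skipped = 0
        for _, feat in features.iterrows():
            start, end = int(feat["start"]), int(feat["end"])
            if end - start < body_bins:
                skipped += 1
                continue
            if feat["chrom"] not in per_chrom:
                continue
            pos, cm, ct = per_chrom[feat["chrom"]]
            strand = feat.get("strand", "+")
            layout = chip.feature_layout_bins(start, end, strand, flank, body_bins, flank_bins)
            for i, (a, b) in enumerate(layout):
                lo = int(np.searchsorted(pos, a, "left"))
                hi = int(np.searchsorted(pos, b, "left"))
                tot = ct[hi] - ct[lo]
                if tot > 0:
                    sums[i] += (cm[hi] - cm[lo]) / tot
                    counts[i] += 1
        if skipped:
            warnings.warn(f"skipped {skipped} features shorter than body_bins bp")
        with np.errstate(invalid="ignore"):
            mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        out[ctx] = pd.DataFrame({"bin_index": np.arange(n_layout), "mean": mean, "n": counts})
    return out


def clone_percent_methylation(reference: str, clones: Sequence[str],
                              clone_strands: Sequence[str] | None = None) -> pd.DataFrame:
    """Single-locus clone analysis of bisulfite-converted sequences.

    Clones are pre-aligned, same length as the reference. For plus-strand
    clones, each reference C is read as C (unconverted, methylated) or T
    (converted); minus-strand clones read reference Gs as G or A. A clone
    base that is neither the reference base nor its conversion product flags
    the clone at that site and excludes it there (count warned).
    """
    if clone_strands is None:
        clone_strands = ["+"] * len(clones)
    if any(len(c) != len(reference) for c in clones):
        raise ValueError("clones must be pre-aligned to the reference length")
    contexts = classify_contexts({"ref": reference}).set_index(["pos", "strand"])["context"]
    rows = []
    n_invalid = 0
    for strand, refbase, unconv, conv in (("+", "C", "C", "T"), ("-", "G", "G", "A")):
        strand_clones = [c.upper() for c, s in zip(clones, clone_strands) if s == strand]
        if not strand_clones:
            continue
        for pos, base in enumerate(reference.upper()):
            if base != refbase:
                continue
            n_unconv = total = 0
            for clone in strand_clones:
                if clone[pos] == unconv:
                    n_unconv += 1
                    total += 1
                elif clone[pos] == conv:
                    total += 1
                else:
                    n_invalid += 1
            if total > 0:
                rows.append((pos, strand, contexts.get((pos, strand), "incomplete"),
                             n_unconv, total, 100.0 * n_unconv / total))
    if n_invalid:
        warnings.warn(f"excluded {n_invalid} clone bases that were neither the "
                      "reference base nor a conversion product")
    return pd.DataFrame(rows, columns=["pos", "strand", "context", "unconverted",
                                       "total", "percent"])
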