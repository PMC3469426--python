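"""ChIP-chip probe normalization, differential H3K9me2 region calling, and
metagene/metaplot profiles.

The caller follows the tiling-array recipe: per-probe log2(IP/input),
per-array centering, 500 bp bins stepped by 250 bp, a mutant-minus-wild-type
difference track Z-transformed genome-wide, a Z < -3 cutoff, and merging of
flagged bins within 2.5 kb. Because both per-bin scores are already log2
quantities, the per-bin difference equals the log2 of the intensity-ratio
quotient between genotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

BIN_COLUMNS = ["chrom", "start", "end", "score", "n_probes"]


class DegenerateTrackError(ValueError):
    pass


def probe_log_ratio(table: pd.DataFrame) -> pd.DataFrame:
    """Add log_ratio = log2(ip/input) to a probe table."""
    bad = (table["ip"] <= 0) | (table["input"] <= 0)
    if bad.any():
        row = table[bad].iloc[0]
        raise ValueError(
            f"nonpositive intensity at {row['chrom']}:{int(row['start'])}-{int(row['end'])}")
    out = table.copy()
    out["log_ratio"] = np.log2(out["ip"] / out["input"])
    return out


def center_scale(values: Sequence[float]) -> np.ndarray:
    """Center one array's scores so their mean is zero."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("at least 2 probes are required to center an array")
    return arr - np.nanmean(arr)


def tile_genome(chrom_sizes: Mapping[str, int], bin: int = 500, step: int = 250) -> pd.DataFrame:
    """Overlapping tiling: bins [k*step, k*step+bin) truncated at chromosome end."""
    if not 0 < step <= bin:
        raise ValueError("require 0 < step <= bin")
    rows = []
    for chrom, length in chrom_sizes.items():
        start = 0
        while start < length:
            rows.append((chrom, start, min(start + bin, length), np.nan, 0))
            start += step
    return pd.DataFrame(rows, columns=BIN_COLUMNS)


def aggregate_bins(probes: pd.DataFrame, bins: pd.DataFrame,
                   value_col: str = "log_ratio") -> pd.DataFrame:
    """Bin score = mean probe value over probes whose midpoint lies in the bin.

    Bins without probes keep a missing (NaN) score, never a silent zero.
    """
    out = bins.copy()
    sums = np.zeros(len(out))
    counts = np.zeros(len(out), dtype=int)
    # per chromosome, map each probe midpoint to every bin containing it
    for chrom, bidx in out.groupby("chrom", sort=False).groups.items():
        bdf = out.loc[bidx]
        if len(bdf) == 0:
            continue
        starts = bdf["start"].to_numpy()
        step = int(starts[1] - starts[0]) if len(starts) > 1 else int(bdf["end"].iloc[0])
        binw = int((bdf["end"] - bdf["start"]).max())
        p = probes[probes["chrom"] == chrom]
        if len(p) == 0:
            continue
        mids = ((p["start"].to_numpy() + p["end"].to_numpy()) // 2).astype(int)
        vals = p[value_col].to_numpy(dtype=float)
        base = bidx.to_numpy()[0]
        n_bins = len(bdf)
        max_per = int(np.ceil(binw / step))
        for j in range(max_per):
            k = mids // step - j
            ok = (k >= 0) & (k < n_bins) & (k * step <= mids) & (mids < k * step + binw)
            np.add.at(sums, base + k[ok], vals[ok])
            np.add.at(counts, base + k[ok], 1)
    with np.errstate(invalid="ignore"):
        out["score"] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    out["n_probes"] = counts
    return out


def zscore_transform(values: Sequence[float]) -> np.ndarray:
    """Z-transform with the population standard deviation; NaN propagates."""
    arr = np.asarray(values, dtype=float)
    finite = arr[~np.isnan(arr)]
    if finite.size < 2:
        raise DegenerateTrackError("need >= 2 non-missing values")
    sd = float(np.std(finite))  # population sd
    if sd == 0:
        raise DegenerateTrackError("zero variance: cannot Z-transform")
    return (arr - float(np.mean(finite))) / sd


def merge_regions(intervals: Sequence[tuple[int, int]], gap: int) -> list[tuple[int, int]]:
    """Union consecutive intervals whose gap (next.start - current.end) <= gap.

    Input must be sorted by start (one chromosome at a time); idempotent.
    """
    intervals = list(intervals)
    if any(intervals[i][0] > intervals[i + 1][0] for i in range(len(intervals) - 1)):
        raise ValueError("intervals must be sorted by start")
    merged: list[list[int]] = []
    for start, end in intervals:
        if merged and start - merged[-1][1] <= gap:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def _check_same_tiling(a: pd.DataFrame, b: pd.DataFrame) -> None:
    if len(a) != len(b) or not (
        a["chrom"].to_numpy() == b["chrom"].to_numpy()
    ).all() or not (a["start"].to_numpy() == b["start"].to_numpy()).all():
        raise ValueError("tracks do not share the same tiling")


def difference_zscores(mutant: pd.DataFrame, wildtype: pd.DataFrame) -> pd.Series:
    """Genome-wide Z-scores of the per-bin mutant-minus-wild-type difference."""
    _check_same_tiling(mutant, wildtype)
    diff = mutant["score"].to_numpy(dtype=float) - wildtype["score"].to_numpy(dtype=float)
    return pd.Series(zscore_transform(diff), index=mutant.index)


def call_decreased_regions(mutant: pd.DataFrame, wildtype: pd.DataFrame,
                           z_cut: float = -3.0, merge_gap: int = 2500,
                           min_bins: int = 3, genotype: str = "mutant") -> pd.DataFrame:
    """Call regions where the mutant signal drops below the wild type.

    Flags bins with difference Z < z_cut, merges flagged bins within
    ``merge_gap`` bp, and reports regions supported by at least ``min_bins``
    flagged bins (isolated sub-threshold bins at the ~Phi(-3) background rate
    are not reported as regions). Missing bins never extend a run, though
    ``merge_gap`` may bridge them.
    """
    z = difference_zscores(mutant, wildtype)
    flagged = mutant[(z < z_cut).to_numpy()].copy()
    flagged["z"] = z[z < z_cut].to_numpy()
    rows = []
    for chrom, fdf in flagged.groupby("chrom", sort=False):
        fdf = fdf.sort_values("start")
        ivals = list(zip(fdf["start"].astype(int), fdf["end"].astype(int)))
        merged = merge_regions(ivals, merge_gap)
        starts = fdf["start"].to_numpy()
        zs = fdf["z"].to_numpy()
        for mstart, mend in merged:
            inside = (starts >= mstart) & (starts < mend)
            n = int(inside.sum())
            if n < min_bins:
                continue
            rows.append((chrom, mstart, mend, float(zs[inside].mean()), n, genotype))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "mean_z", "n_bins", "genotype"])


# --- metagene / metaplot ------------------------------------------------------

def feature_layout_bins(start: int, end: int, strand: str, flank: int,
                        body_bins: int, flank_bins: int) -> list[tuple[int, int]]:
    """Genomic intervals for each layout bin of one feature, 5'-most first.

    Layout: ``flank_bins`` fixed-width upstream bins, ``body_bins`` linearly
    scaled body bins, ``flank_bins`` downstream bins. Minus-strand features
    are reversed so index 0 is always the 5'-most upstream bin.
    """
    up = [(start - flank + i * flank // flank_bins,
           start - flank + (i + 1) * flank // flank_bins) for i in range(flank_bins)]
    edges = np.linspace(start, end, body_bins + 1).round().astype(int)
    body = [(int(edges[i]), int(edges[i + 1])) for i in range(body_bins)]
    down = [(end + i * flank // flank_bins,
             end + (i + 1) * flank // flank_bins) for i in range(flank_bins)]
    bins = up + body + down
    if strand == "-":
        # reflect about the feature: swap flanks and reverse everything
        bins = bins[::-1]
    return bins


class _TrackIndex:
    """Fast interval-mean lookup over a BinTrack with a regular tiling."""

    def __init__(self, track: pd.DataFrame):
        self.per_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, cdf in track.groupby("chrom", sort=False):
            cdf = cdf.sort_values("start")
            self.per_chrom[chrom] = (cdf["start"].to_numpy(), cdf["end"].to_numpy(),
                                     cdf["score"].to_numpy(dtype=float))

    def mean(self, chrom: str, a: int, b: int) -> float:
        if chrom not in self.per_chrom or b <= a:
            return np.nan
        starts, ends, scores = self.per_chrom[chrom]
        lo = int(np.searchsorted(ends, a, side="right"))
        hi = int(np.searchsorted(starts, b, side="left"))
        if hi <= lo:
            return np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return float(np.nanmean(scores[lo:hi]))


def metaprofile(track: pd.DataFrame, features: pd.DataFrame, flank: int = 2000,
                body_bins: int = 40, flank_bins: int = 20) -> pd.DataFrame:
    """Average signal profile over stranded features with scaled bodies.

    ``features`` needs chrom/start/end and optionally strand. Features
    shorter than ``body_bins`` bp are skipped (count warned). Missing track
    bins are averaged away per profile bin rather than counted as zero.
    """
    if len(features) == 0:
        raise ValueError("features must be nonempty")
    if flank < 0:
        raise ValueError("flank must be >= 0")
    index = _TrackIndex(track)
    n_layout = body_bins + 2 * flank_bins
    sums = np.zeros(n_layout)
    counts = np.zeros(n_layout, dtype=int)
    skipped = 0
    for _, feat in features.iterrows():
        start, end = int(feat["start"]), int(feat["end"])
        if end - start < body_bins:
            skipped += 1
            continue
        strand = feat.get("strand", "+")
        for i, (a, b) in enumerate(feature_layout_bins(start, end, strand, flank,
                                                       body_bins, flank_bins)):
            v = index.mean(feat["chrom"], a, b)
            if not np.isnan(v):
                sums[i] += v
                counts[i] += 1
    if skipped:
        warnings.warn(f"skipped {skipped} features shorter than body_bins bp")
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame({"bin_index": np.arange(n_layout), "mean": mean, "n": counts})


def geneset_signal_summary(tracks: Mapping[str, pd.DataFrame], genes: pd.DataFrame,
                           window: str = "body", upstream: int = 0
                           ) -> tuple[pd.DataFrame, pd.DataFrame, float | None]:
    """Per-gene mean track signal and a between-genotype rank-sum comparison.

    ``window`` is 'body' or 'body+upstream' (strand-aware ``upstream`` bp
    added before the TSS). Genes with no covered bins are excluded (count
    warned). Returns (per-gene table, per-genotype quartile summary, and a
    Mann-Whitney p-value between the first two genotypes, descriptive only).
    """
    if window not in ("body", "body+upstream"):
        raise ValueError("window must be 'body' or 'body+upstream'")
    per_gene: dict[str, dict[str, float]] = {}
    for genotype, track in tracks.items():
        index = _TrackIndex(track)
        for _, g in genes.iterrows():
            start, end = int(g["start"]), int(g["end"])
            if window == "body+upstream":
                if g.get("strand", "+") == "+":
                    start -= upstream
                else:
                    end += upstream
            v = index.mean(g["chrom"], start, end)
            per_gene.setdefault(g["id"], {})[genotype] = v
    table = pd.DataFrame.from_dict(per_gene, orient="index")
    table.index.name = "gene_id"
    n_dropped = int(table.isna().any(axis=1).sum())
    if n_dropped:
        warnings.warn(f"excluded {n_dropped} genes with no covered bins")
    table = table.dropna()
    summary = table.describe().loc[["25%", "50%", "75%"]]
    pvalue = None
    names = list(tracks)
    if len(names) >= 2 and len(table) >= 2:
        pvalue = float(stats.mannwhitneyu(table[names[0]], table[names[1]],
                                          alternative="two-sided").pvalue)
    return table.reset_index(), summary, pvalue
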