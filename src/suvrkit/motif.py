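"""Position-weight-matrix motif discovery and scanning.

The zinc-finger binding site is modelled as a PWM scored in log-odds bits
against a background base composition (uniform by default). Occurrence
p-values are exact: the null distribution of the log-odds score of a random
w-mer drawn from the background is computed by dynamic programming over the
per-position score distributions, discretized to 1e-3 bits. Motif discovery
from selected read pools uses a ZOOPS (zero-or-one occurrence per sequence)
EM, seeded from strand-collapsed k-mer enrichment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# byte-level lookup used to vectorize sequence encoding; N and anything
# unexpected map to -1
_ENCODE_LUT = np.full(256, -1, dtype=np.int8)
for _b, _i in _BASE_INDEX.items():
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i

DEFAULT_SCALE = 1000  # discretization: scores rounded to 1e-3 bits


class InvalidSequenceError(ValueError):
    pass


class UnattainableThresholdError(ValueError):
    pass


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    for i, ch in enumerate(seq):
        if ch.upper() not in "ACGTN":
            raise InvalidSequenceError(f"invalid character {ch!r} at position {i}")
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes (A=0,C=1,G=2,T=3, other=-1)."""
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class Pwm:
    """Per-position base-frequency matrix with a background model.

    ``freq`` is a (width x 4) matrix over A,C,G,T; every row sums to one and
    every entry is strictly positive (enforce with a pseudocount when
    building from sites). Scores are log2(freq/background) "bits".
    """

    freq: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.0
    name: str = "motif"

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.freq.ndim != 2 or self.freq.shape[1] != 4:
            raise ValueError("freq must be a width x 4 matrix")
        if not 1 <= self.width <= 32:
            raise ValueError(f"width must be in [1, 32], got {self.width}")
        if not np.allclose(self.freq.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("every freq row must sum to 1")
        if np.any(self.freq < 0):
            raise ValueError("frequencies must be non-negative")
        if np.any(self.background <= 0) or not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must be a positive probability 4-vector")
        self._dist_cache: dict[int, "ScoreDistribution"] = {}

    @property
    def width(self) -> int:
        return self.freq.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        # zero frequencies (legal when built without a pseudocount) would give
        # -inf; floor them at 2^-30 so scoring and the p-value DP stay finite
        return np.log2(np.maximum(self.freq, 2.0 ** -30) / self.background)

    def reverse_complement(self) -> "Pwm":
        return Pwm(self.freq[::-1, ::-1].copy(), self.background[::-1].copy(),
                   self.pseudocount, self.name + "_rc")

    def information_content(self) -> float:
        """Total information content in bits relative to the background."""
        return float(np.sum(np.where(self.freq > 0, self.freq * self.log_odds, 0.0)))

    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    def min_score(self) -> float:
        return float(self.log_odds.min(axis=1).sum())

    def distribution(self, scale: int = DEFAULT_SCALE) -> "ScoreDistribution":
        if scale not in self._dist_cache:
            self._dist_cache[scale] = ScoreDistribution(self, scale)
        return self._dist_cache[scale]


def build_pwm(sites: Sequence[str], pseudocount: float = 0.5,
              background: np.ndarray | None = None, name: str = "motif") -> Pwm:
    """Estimate a PWM from equal-length sites.

    freq[i][b] = (count[i][b] + pseudocount) / (n + 4*pseudocount).
    pseudocount=0 is only valid when every column contains all four bases.
    """
    if len(sites) == 0:
        raise ValueError("at least one site is required")
    width = len(sites[0])
    if any(len(s) != width for s in sites):
        raise ValueError("all sites must have equal length")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    counts = np.zeros((width, 4))
    for site in sites:
        codes = encode(site)
        if np.any(codes < 0):
            bad = int(np.argmax(codes < 0))
            raise InvalidSequenceError(f"invalid character in site {site!r} at position {bad}")
        counts[np.arange(width), codes] += 1
    freq = (counts + pseudocount) / (len(sites) + 4 * pseudocount)
    bg = np.full(4, 0.25) if background is None else background
    return Pwm(freq, bg, pseudocount, name)


def consensus_pwm(motif: str, match: float = 1.0, pseudocount: float = 1e-6) -> Pwm:
    """PWM concentrated on a consensus word; useful as a planted-truth model."""
    w = len(motif)
    codes = encode(motif)
    freq = np.full((w, 4), (1 - match) / 3 + pseudocount)
    freq[np.arange(w), codes] = match + pseudocount
    freq /= freq.sum(axis=1, keepdims=True)
    return Pwm(freq, name=f"consensus_{motif}")


def consensus(pwm: Pwm) -> str:
    """Most frequent base per position; ties resolved in fixed order A<C<G<T."""
    best = pwm.freq.argmax(axis=1)  # argmax takes the first max: A<C<G<T order
    n_tied = (np.isclose(pwm.freq, pwm.freq.max(axis=1, keepdims=True))).sum(axis=1)
    if np.any(n_tied > 1):
        warnings.warn("consensus has tied columns; ties broken in base order A<C<G<T")
    return "".join(BASES[i] for i in best)


def log_odds_score(pwm: Pwm, window: str, n_policy: str = "skip") -> float:
    """Exact log-odds score (bits) of one width-length window.

    N handling: ``skip`` raises on N (callers skip such windows), ``background``
    scores N positions 0 bits.
    """
    if len(window) != pwm.width:
        raise ValueError(f"window length {len(window)} != pwm width {pwm.width}")
    codes = encode(window)
    lo = pwm.log_odds
    if np.any(codes < 0):
        if n_policy == "background":
            return float(sum(lo[i, c] for i, c in enumerate(codes) if c >= 0))
        raise InvalidSequenceError("window contains N (default policy skips such windows)")
    return float(lo[np.arange(pwm.width), codes].sum())


class ScoreDistribution:
    """Exact null distribution of the discretized log-odds score.

    Scores are rounded to ``1/scale`` bits per position and the distribution
    of their sum under the background is built by position-wise convolution.
    """

    def __init__(self, pwm: Pwm, scale: int = DEFAULT_SCALE):
        self.pwm = pwm
        self.scale = scale
        self.int_scores = np.rint(pwm.log_odds * scale).astype(np.int64)  # w x 4
        lo = int(self.int_scores.min(axis=1).sum())
        hi = int(self.int_scores.max(axis=1).sum())
        mass = np.zeros(hi - lo + 1)
        # running support starts at the cumulative minimum
        cur_lo = 0
        cur = np.array([1.0])
        for i in range(pwm.width):
            row = self.int_scores[i]
            new_lo = cur_lo + int(row.min())
            new_len = len(cur) + int(row.max() - row.min())
            new = np.zeros(new_len)
            for b in range(4):
                off = int(row[b]) - int(row.min())
                new[off:off + len(cur)] += cur * pwm.background[b]
            cur, cur_lo = new, new_lo
        mass[cur_lo - lo: cur_lo - lo + len(cur)] = cur
        self.offset = lo
        self.mass = mass
        # tail[i] = P(int score >= offset + i)
        self.tail = np.cumsum(mass[::-1])[::-1]
        self._min_tail = float(self.tail[np.nonzero(self.mass)[0][-1]])

    def pvalue_int(self, int_score: int) -> float:
        idx = int_score - self.offset
        if idx <= 0:
            return 1.0
        if idx >= len(self.tail):
            # above the attainable maximum: by convention return the mass of
            # the best word(s), never 0 (>= 4^-w under a uniform background)
            return self._min_tail
        p = float(self.tail[idx])
        return p if p > 0 else self._min_tail

    def pvalue(self, score: float) -> float:
        return self.pvalue_int(int(np.rint(score * self.scale)))

    def threshold_int(self, alpha: float) -> int:
        if not 0 < alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if alpha < self._min_tail:
            raise UnattainableThresholdError(
                f"alpha={alpha} below the smallest attainable p-value {self._min_tail:.3g}")
        # minimal integer score whose tail is <= alpha
        idx = int(np.searchsorted(-self.tail, -alpha, side="left"))
        return self.offset + idx

    def threshold(self, alpha: float) -> float:
        return self.threshold_int(alpha) / self.scale


def score_pvalue(pwm: Pwm, score: float, scale: int = DEFAULT_SCALE) -> float:
    """P(log-odds >= score) for a random w-mer from the background."""
    return pwm.distribution(scale).pvalue(score)


def pvalue_threshold_score(pwm: Pwm, alpha: float, scale: int = DEFAULT_SCALE) -> float:
    """Minimal score s with score_pvalue(s) <= alpha."""
    return pwm.distribution(scale).threshold(alpha)


@dataclass
class MotifHit:
    chrom: str
    start: int
    strand: str
    score: float
    pvalue: float


def _window_int_scores(int_scores: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Discretized scores of all windows of one encoded sequence.

    Windows containing N (code -1) get a score of iinfo.min so they never
    pass any threshold.
    """
    w = int_scores.shape[0]
    m = len(codes) - w + 1
    if m <= 0:
        return np.empty(0, dtype=np.int64)
    total = np.zeros(m, dtype=np.int64)
    bad = np.zeros(m, dtype=bool)
    for i in range(w):
        seg = codes[i:i + m]
        bad |= seg < 0
        total += int_scores[i, np.clip(seg, 0, 3)]
    total[bad] = np.iinfo(np.int64).min // 2
    return total


def scan_sequence(pwm: Pwm, seq: str, name: str = "seq", alpha: float = 0.001,
                  both_strands: bool = True, scale: int = DEFAULT_SCALE) -> list[MotifHit]:
    """All windows with occurrence p-value <= alpha, sorted by start then strand.

    Windows containing N are skipped. Minus-strand hits are reported at the
    0-based start of the window on the forward sequence.
    """
    if len(seq) < pwm.width:
        warnings.warn(f"sequence {name!r} shorter than motif width; no hits")
        return []
    codes = encode(seq)
    hits: list[MotifHit] = []
    strands = [("+", pwm)] + ([("-", pwm.reverse_complement())] if both_strands else [])
    for strand, model in strands:
        dist = model.distribution(scale)
        scores = _window_int_scores(dist.int_scores, codes)
        try:
            thr = dist.threshold_int(alpha)
        except UnattainableThresholdError:
            continue
        for j in np.nonzero(scores >= thr)[0]:
            s = int(scores[j])
            hits.append(MotifHit(name, int(j), strand, s / scale, dist.pvalue_int(s)))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scan_genome(pwm: Pwm, chromosomes: dict[str, str], alpha: float = 0.001,
                both_strands: bool = True) -> pd.DataFrame:
    """scan_sequence over every chromosome, returned as one table."""
    rows = []
    for chrom, seq in chromosomes.items():
        for h in scan_sequence(pwm, seq, chrom, alpha, both_strands):
            rows.append((h.chrom, h.start, h.start + pwm.width, h.strand, h.score, h.pvalue))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "score", "pvalue"])


def best_scores(pwm: Pwm, reads: Sequence[str], both_strands: bool = True) -> np.ndarray:
    """Best window log-odds score (bits) per read, over both strands."""
    fwd = pwm.distribution().int_scores
    rev = pwm.reverse_complement().distribution().int_scores
    out = np.empty(len(reads))
    for i, read in enumerate(reads):
        codes = encode(read)
        s = _window_int_scores(fwd, codes)
        if both_strands:
            s = np.concatenate([s, _window_int_scores(rev, codes)])
        out[i] = s.max() / DEFAULT_SCALE if len(s) else -np.inf
    return out


def kmer_enrichment(selected_reads: Sequence[str], control_reads: Sequence[str],
                    k: int = 8) -> pd.DataFrame:
    """Strand-collapsed k-mer log2 enrichment of selected over control reads.

    A k-mer and its reverse complement are pooled into one row keyed by the
    lexicographically smaller of the two. +1 smoothing keeps ratios finite.
    """
    if not selected_reads or not control_reads:
        raise ValueError("both read sets must be nonempty")

    def count(reads: Sequence[str]) -> tuple[dict[str, int], int]:
        counts: dict[str, int] = {}
        total = 0
        for read in reads:
            read = read.upper()
            for j in range(len(read) - k + 1):
                kmer = read[j:j + k]
                if any(c not in _BASE_INDEX for c in kmer):
                    continue
                canon = min(kmer, reverse_complement(kmer))
                counts[canon] = counts.get(canon, 0) + 1
                total += 1
        return counts, total

    sel, n_sel = count(selected_reads)
    ctl, n_ctl = count(control_reads)
    kmers = sorted(set(sel) | set(ctl))
    rows = []
    for kmer in kmers:
        fs = (sel.get(kmer, 0) + 1) / (n_sel + len(kmers))
        fc = (ctl.get(kmer, 0) + 1) / (n_ctl + len(kmers))
        rows.append((kmer, sel.get(kmer, 0), ctl.get(kmer, 0), np.log2(fs / fc)))
    df = pd.DataFrame(rows, columns=["kmer", "selected_count", "control_count", "log2_enrichment"])
    return df.sort_values("log2_enrichment", ascending=False, kind="mergesort").reset_index(drop=True)


@dataclass
class DiscoveredMotif:
    pwm: Pwm
    sites: pd.DataFrame            # read_index, position, strand, posterior
    gamma: float                   # fraction of reads estimated to carry a site
    log_likelihood: float          # relative to the all-background model
    ll_history: list[float]
    converged: bool
    no_motif: bool                 # information content below the floor
    width_scores: dict[int, float] | None = None

    @property
    def consensus(self) -> str:
        return consensus(self.pwm)


def _zoops_em(groups: list[np.ndarray], width: int, init_freq: np.ndarray,
              background: np.ndarray, max_iter: int, tol: float,
              pseudocount: float) -> tuple[np.ndarray, float, list[float], bool, list]:
    """Run ZOOPS EM on reads grouped by equal length (each group an n x L matrix)."""
    freq = init_freq.copy()
    gamma = 0.5
    ll_history: list[float] = []
    converged = False
    n_reads = sum(g.shape[0] for g in groups)
    prev_state = None
    for _ in range(max_iter):
        log_ratio = np.log2(freq / background[None, :])  # w x 4
        counts = np.full((width, 4), pseudocount)
        total_post = 0.0
        ll = 0.0
        per_group_post = []
        for g in groups:
            n, length = g.shape
            m = length - width + 1
            lr_f = np.zeros((n, m))
            lr_r = np.zeros((n, m))
            for i in range(width):
                lr_f += log_ratio[i][g[:, i:i + m]]
                # minus-strand window at j: motif position i reads complement
                # of the base at j + width-1-i
                lr_r += log_ratio[i][3 - g[:, width - 1 - i: width - 1 - i + m]]
            lr = np.concatenate([2.0 ** lr_f, 2.0 ** lr_r], axis=1)  # n x 2m
            prior = gamma / (2 * m)
            denom = (1 - gamma) + prior * lr.sum(axis=1)
            post = (prior * lr) / denom[:, None]
            ll += float(np.log(denom).sum())
            post_f, post_r = post[:, :m], post[:, m:]
            for i in range(width):
                seg_f = g[:, i:i + m]
                seg_r = 3 - g[:, width - 1 - i: width - 1 - i + m]
                for b in range(4):
                    counts[i, b] += float((post_f * (seg_f == b)).sum())
                    counts[i, b] += float((post_r * (seg_r == b)).sum())
            total_post += float(post.sum())
            per_group_post.append((post_f, post_r))
        if ll_history and ll < ll_history[-1] - 1e-9:
            # the pseudocount is a MAP prior, so the data likelihood can dip
            # slightly near a fixed point; revert to the previous state
            freq, gamma, per_group_post = prev_state
            converged = True
            break
        ll_history.append(ll)
        if len(ll_history) >= 2 and ll - ll_history[-2] < tol:
            converged = True
            break
        prev_state = (freq, gamma, per_group_post)
        gamma = min(max(total_post / n_reads, 1e-4), 1 - 1e-4)
        freq = counts / counts.sum(axis=1, keepdims=True)
    return freq, gamma, ll_history, converged, per_group_post


def discover_motif(reads: Sequence[str], width: int | tuple[int, int] = 8,
                   restarts: int = 5, seed: int = 0, max_iter: int = 200,
                   tol: float = 1e-4, pseudocount: float = 0.25,
                   ic_floor: float = 6.0, width_penalty: float | None = None,
                   background: np.ndarray | None = None) -> DiscoveredMotif:
    """ZOOPS EM motif discovery on a pool of reads.

    Each read holds zero or one site, on either strand. EM is initialized
    from the most enriched strand-collapsed k-mers plus ``restarts`` random
    site samplings; the highest-likelihood model wins. When ``width`` is a
    (lo, hi) range, the width with the largest per-column-penalized
    log-likelihood ratio is selected (penalty defaults to 1.5*ln(n_reads)
    per column, a BIC-style charge for the 3 free parameters of a column).
    """
    if len(reads) < 20:
        raise ValueError("at least 20 reads are required")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    widths = [width] if isinstance(width, int) else list(range(width[0], width[1] + 1))
    if min(widths) < 4:
        raise ValueError("width must be >= 4")
    rng = np.random.default_rng(seed)

    # group reads by length for batched EM
    by_len: dict[int, list[np.ndarray]] = {}
    clean_reads = []
    for read in reads:
        codes = encode(read)
        codes = np.where(codes < 0, rng.integers(0, 4, len(codes)), codes)  # Ns randomized
        clean_reads.append(codes)
        by_len.setdefault(len(codes), []).append(codes)
    groups = [np.vstack(v) for _, v in sorted(by_len.items()) if len(v[0]) >= max(widths)]
    if not groups:
        raise ValueError("reads shorter than motif width")
    n_reads = sum(g.shape[0] for g in groups)
    if width_penalty is None:
        width_penalty = 1.5 * np.log(n_reads)

    best_per_width: dict[int, tuple] = {}
    for w in widths:
        # seed PWMs: top canonical k-mers by raw count, plus random site draws
        kmer_counts: dict[str, int] = {}
        for codes in clean_reads[:500]:
            s = "".join(BASES[c] for c in codes)
            for j in range(len(s) - w + 1):
                canon = min(s[j:j + w], reverse_complement(s[j:j + w]))
                kmer_counts[canon] = kmer_counts.get(canon, 0) + 1
        top = sorted(kmer_counts, key=kmer_counts.get, reverse=True)[:3]
        inits = [consensus_pwm(kmer, match=0.7, pseudocount=0.01).freq for kmer in top]
        for _ in range(restarts):
            sites = []
            for g in groups:
                rows = rng.choice(g.shape[0], size=min(30, g.shape[0]), replace=False)
                for r in rows:
                    j = rng.integers(0, g.shape[1] - w + 1)
                    sites.append(g[r, j:j + w])
            counts = np.full((w, 4), 1.0)
            for site in sites:
                counts[np.arange(w), site] += 1
            inits.append(counts / counts.sum(axis=1, keepdims=True))
        best = None
        for init in inits:
            freq, gamma, hist, conv, post = _zoops_em(groups, w, init, bg, max_iter, tol, pseudocount)
            if best is None or hist[-1] > best[2][-1]:
                best = (freq, gamma, hist, conv, post)
        best_per_width[w] = best

    width_scores = {w: best_per_width[w][2][-1] - width_penalty * w for w in widths}
    w_star = max(width_scores, key=width_scores.get)
    freq, gamma, hist, conv, per_group_post = best_per_width[w_star]
    pwm = Pwm(freq, bg, pseudocount, name="discovered")
    if not conv:
        warnings.warn("EM did not converge within max_iter; returning best-so-far")

    # best-site table from final posteriors
    rows = []
    read_idx = 0
    for g, (post_f, post_r) in zip([np.vstack(v) for _, v in sorted(by_len.items())
                                    if len(v[0]) >= max(widths)], per_group_post):
        post = np.concatenate([post_f, post_r], axis=1)
        m = post_f.shape[1]
        best_j = post.argmax(axis=1)
        best_p = post.max(axis=1)
        for r in range(g.shape[0]):
            j = int(best_j[r])
            strand = "+" if j < m else "-"
            rows.append((read_idx, j % m, strand, float(best_p[r])))
            read_idx += 1
    sites = pd.DataFrame(rows, columns=["read_index", "position", "strand", "posterior"])
    no_motif = pwm.information_content() < ic_floor
    return DiscoveredMotif(pwm, sites, float(gamma), float(hist[-1]), hist, conv,
                           no_motif, width_scores if len(widths) > 1 else None)


# --- minimal MEME text format -------------------------------------------------

def write_meme(path: str | Path, pwm: Pwm, nsites: int = 20) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {p:.6f}" for b, p in zip(BASES, pwm.background)) + "\n\n")
        fh.write(f"MOTIF {pwm.name}\n")
        fh.write(f"letter-probability matrix: alength= 4 w= {pwm.width} "
                 f"nsites= {nsites} E= 0\n")
        for row in pwm.freq:
            fh.write(" " + " ".join(f"{p:.6f}" for p in row) + "\n")


def read_meme(path: str | Path) -> Pwm:
    background = np.full(4, 0.25)
    name = "motif"
    rows: list[list[float]] = []
    width = None
    with open(path) as fh:
        lines = iter(fh.read().splitlines())
    for line in lines:
        line = line.strip()
        if line.startswith("Background letter frequencies"):
            vals = next(lines).split()
            background = np.array([float(vals[i]) for i in range(1, 8, 2)])
        elif line.startswith("MOTIF"):
            name = line.split()[1]
        elif line.startswith("letter-probability matrix"):
            for tok in line.replace(":", " ").split():
                if width is None and tok == "w=":
                    width = -1
                elif width == -1:
                    width = int(tok)
            for _ in range(width):
                rows.append([float(x) for x in next(lines).split()])
    if not rows:
        raise ValueError(f"no letter-probability matrix found in {path}")
    return Pwm(np.array(rows), background, name=name)


def hits_to_bed(hits: pd.DataFrame, path: str | Path, motif_id: str = "motif") -> None:
    """Write hits as BED6 (score = round(1000*bits)) plus a TSV with exact p-values."""
    from . import io as _io
    df = hits.copy()
    df["name"] = motif_id
    _io.write_bed(path, df, score_col="score", name_col="name", scale=1000)
    _io.write_tsv(str(path) + ".pvalues.tsv", hits)
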