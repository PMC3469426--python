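"""Synthetic genomes and data layers with planted ground truth.

Every simulator here emits both the data files a real experiment would
produce and a truth table of what was planted, so each downstream caller
can be tested by recovery. The default scale — two chromosomes of 200 kb,
100 genes, 60 transposable elements with a central pericentromeric block —
is large enough for metaplots and region calling yet runs in seconds.

Layers emulated:

* a multi-chromosome genome with pericentromeres, genes and TEs;
* TACTAGTA binding sites written into gene promoters;
* SELEX: iterative biased resampling of an oligo or genomic-fragment pool,
  with retention probability logistic in the best PWM log-odds score;
* H3K9me2 tiling arrays for wild type and mutant genotypes with planted
  depleted patches (some shared between genotypes, some exclusive, and some
  deliberately free of DNA methylation);
* a per-cytosine methylome with compartment/context-specific levels that is
  unchanged between genotypes at the methylation-independent patches;
* RNA-seq counts with up-regulated gene sets planted identically across
  genotypes (the epistatic design).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as _io
from .methylation import Methylome, classify_contexts
from .motif import BASES, Pwm, best_scores, encode, reverse_complement

DEFAULT_MOTIF = "TACTAGTA"


class PlacementError(RuntimeError):
    pass


class DegenerateSelectionError(RuntimeError):
    pass


@dataclass
class GeneModel:
    id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str
    baseline_expression: float

    def __post_init__(self) -> None:
        if not self.end > self.start >= 0:
            raise ValueError(f"degenerate gene interval for {self.id}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end


@dataclass
class Feature:
    id: str
    chrom: str
    start: int
    end: int
    strand: str
    kind: str = "transposable_element"


@dataclass
class TruthTable:
    """Planted ground truth for recovery tests."""

    motif_sites: pd.DataFrame | None = None       # chrom, pos, strand, gene_id
    depleted_regions: pd.DataFrame | None = None  # chrom, start, end, genotypes, meth_independent
    de_genes: pd.DataFrame | None = None          # genotype, gene_id, fold

    def write(self, outdir: str | Path) -> None:
        import json
        outdir = Path(outdir)
        for name in ("motif_sites", "depleted_regions", "de_genes"):
            df = getattr(self, name)
            if df is not None:
                df.to_csv(outdir / f"truth_{name}.tsv", sep="\t", index=False)
                with open(outdir / f"truth_{name}.json", "w") as fh:
                    json.dump(df.to_dict(orient="records"), fh, indent=2,
                              default=str)
                    fh.write("\n")


@dataclass
class SyntheticGenome:
    chromosomes: dict[str, str]
    pericentromeres: dict[str, list[tuple[int, int]]]
    genes: list[GeneModel]
    tes: list[Feature]
    seed: int

    def chrom_sizes(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    def genes_frame(self) -> pd.DataFrame:
        return pd.DataFrame([(g.id, g.chrom, g.start, g.end, g.strand,
                              g.baseline_expression) for g in self.genes],
                            columns=["id", "chrom", "start", "end", "strand",
                                     "baseline_expression"])

    def tes_frame(self) -> pd.DataFrame:
        return pd.DataFrame([(t.id, t.chrom, t.start, t.end, t.strand) for t in self.tes],
                            columns=["id", "chrom", "start", "end", "strand"])

    def write_fasta(self, path: str | Path) -> None:
        _io.write_fasta(path, self.chromosomes)

    def write_gff3(self, path: str | Path) -> None:
        records = []
        for chrom, blocks in self.pericentromeres.items():
            for i, (s, e) in enumerate(blocks):
                records.append({"seqid": chrom, "type": "pericentromeric_region",
                                "start": s, "end": e,
                                "attributes": {"ID": f"peri_{chrom}_{i}"}})
        for g in self.genes:
            records.append({"seqid": g.chrom, "type": "gene", "start": g.start,
                            "end": g.end, "strand": g.strand,
                            "attributes": {"ID": g.id}})
        for t in self.tes:
            records.append({"seqid": t.chrom, "type": "transposable_element",
                            "start": t.start, "end": t.end, "strand": t.strand,
                            "attributes": {"ID": t.id}})
        _io.write_gff3(path, records)

    def in_pericentromere(self, chrom: str, start: int, end: int) -> bool:
        return any(start < e and end > s for s, e in self.pericentromeres.get(chrom, []))


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(BASES))[rng.choice(4, size=length, p=probs)])


def make_genome(seed: int, n_chrom: int = 2, chrom_length: int = 200_000,
                gc: float = 0.36, n_genes: int = 100, n_tes: int = 60,
                pericentromere_fraction: float = 0.25,
                te_pericentromere_enrichment: float = 0.85,
                gene_length: tuple[int, int] = (800, 2500),
                te_length: tuple[int, int] = (300, 1500),
                feature_gap: int = 100, max_tries: int = 2000) -> SyntheticGenome:
    """Random genome with central pericentromeres, genes in the arms and TEs
    preferentially inside pericentromeres.

    Deterministic for a fixed seed; placement keeps features at least
    ``feature_gap`` bp apart. Raises PlacementError naming the first
    unplaceable feature.
    """
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    chromosomes = {}
    pericentromeres: dict[str, list[tuple[int, int]]] = {}
    for i in range(n_chrom):
        name = f"chr{i + 1}"
        chromosomes[name] = _random_dna(rng, chrom_length, gc)
        if pericentromere_fraction > 0:
            half = int(chrom_length * pericentromere_fraction / 2)
            mid = chrom_length // 2
            pericentromeres[name] = [(mid - half, mid + half)]
        else:
            pericentromeres[name] = []

    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chromosomes}

    def place(chrom: str, length: int, inside_peri: bool, label: str) -> tuple[int, int]:
        # sample uniformly over the free space of the target compartment
        L = len(chromosomes[chrom])
        peri = pericentromeres[chrom]
        if inside_peri and peri:
            allowed = list(peri)
        elif peri:
            allowed = []
            prev = 0
            for s, e in sorted(peri):
                if s > prev:
                    allowed.append((prev, s))
                prev = e
            if prev < L:
                allowed.append((prev, L))
        else:
            allowed = [(0, L)]
        blocked = sorted(occupied[chrom])
        segments: list[tuple[int, int]] = []
        for a_start, a_end in allowed:
            cursor = a_start
            for b_start, b_end in blocked:
                if b_end + feature_gap <= cursor or b_start - feature_gap >= a_end:
                    continue
                if b_start - feature_gap > cursor:
                    segments.append((cursor, b_start - feature_gap))
                cursor = max(cursor, b_end + feature_gap)
            if cursor < a_end:
                segments.append((cursor, a_end))
        slots = np.array([max(0, e - s - length + 1) for s, e in segments])
        if slots.sum() == 0:
            raise PlacementError(f"no room to place {label} on {chrom}")
        seg = int(rng.choice(len(segments), p=slots / slots.sum()))
        start = int(rng.integers(segments[seg][0], segments[seg][1] - length + 1))
        end = start + length
        occupied[chrom].append((start, end))
        return start, end

    genes: list[GeneModel] = []
    chrom_names = list(chromosomes)
    for i in range(n_genes):
        chrom = chrom_names[i % n_chrom]
        length = int(rng.integers(gene_length[0], gene_length[1] + 1))
        start, end = place(chrom, length, inside_peri=False, label=f"gene_{i:04d}")
        strand = "+" if rng.random() < 0.5 else "-"
        baseline = float(rng.lognormal(mean=np.log(50), sigma=1.0))
        genes.append(GeneModel(f"gene_{i:04d}", chrom, start, end, strand, baseline))
    tes: list[Feature] = []
    for i in range(n_tes):
        chrom = chrom_names[i % n_chrom]
        length = int(rng.integers(te_length[0], te_length[1] + 1))
        inside = (rng.random() < te_pericentromere_enrichment
                  and pericentromere_fraction > 0)
        start, end = place(chrom, length, inside_peri=inside, label=f"te_{i:04d}")
        strand = "+" if rng.random() < 0.5 else "-"
        tes.append(Feature(f"te_{i:04d}", chrom, start, end, strand))
    genes.sort(key=lambda g: (g.chrom, g.start))
    tes.sort(key=lambda t: (t.chrom, t.start))
    return SyntheticGenome(chromosomes, pericentromeres, genes, tes, seed)


def plant_motif_sites(genome: SyntheticGenome, motif: str = DEFAULT_MOTIF,
                      gene_fraction: float = 0.4, upstream_window: int = 1000,
                      seed: int = 0) -> tuple[SyntheticGenome, TruthTable]:
    """Write one motif copy into the upstream window of a gene fraction.

    The site is written in the gene's sense orientation (reverse complement
    on minus-strand genes; for a palindromic motif the two are identical).
    Sites whose window runs off the chromosome are skipped with a warning,
    and the truth table reflects actual placements only.
    """
    if not 0 <= gene_fraction <= 1:
        raise ValueError("gene_fraction must be in [0, 1]")
    if len(motif) > upstream_window:
        raise ValueError("motif longer than upstream window")
    rng = np.random.default_rng(seed)
    n_target = round(gene_fraction * len(genome.genes))
    chosen = sorted(rng.choice(len(genome.genes), size=n_target, replace=False))
    seqs = {c: bytearray(s, "ascii") for c, s in genome.chromosomes.items()}
    rows = []
    skipped = 0
    for gi in chosen:
        gene = genome.genes[gi]
        offset = int(rng.integers(0, upstream_window - len(motif) + 1))
        if gene.strand == "+":
            pos = gene.start - upstream_window + offset
            site = motif
        else:
            pos = gene.end + upstream_window - offset - len(motif)
            site = reverse_complement(motif)
        if pos < 0 or pos + len(motif) > len(seqs[gene.chrom]):
            skipped += 1
            continue
        seqs[gene.chrom][pos:pos + len(motif)] = site.encode("ascii")
        rows.append((gene.chrom, pos, gene.strand, gene.id))
    if skipped:
        warnings.warn(f"skipped {skipped} motif sites with windows off the chromosome")
    new_genome = SyntheticGenome({c: s.decode("ascii") for c, s in seqs.items()},
                                 genome.pericentromeres, genome.genes, genome.tes,
                                 genome.seed)
    truth = TruthTable(motif_sites=pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "gene_id"]))
    return new_genome, truth


# --- SELEX --------------------------------------------------------------------

@dataclass
class SelexPool:
    """A pool of candidate binding substrates; genomic pools carry origins."""

    reads: list[str]
    origins: pd.DataFrame | None = None  # chrom, start, end, strand per read


def random_oligo_pool(n: int, seed: int, core: int = 15,
                      flank5: str = "GGATCC", flank3: str = "GAATTC") -> SelexPool:
    """Oligos with a random core between fixed flanks (in-vitro SELEX design)."""
    rng = np.random.default_rng(seed)
    bases = np.array(list(BASES))
    reads = [flank5 + "".join(bases[rng.integers(0, 4, core)]) + flank3
             for _ in range(n)]
    return SelexPool(reads)


def genomic_fragment_pool(genome: SyntheticGenome, n: int, seed: int,
                          fragment_length: int = 100) -> SelexPool:
    """Uniform random genomic fragments (gSELEX design), random strand."""
    rng = np.random.default_rng(seed)
    chrom_names = list(genome.chromosomes)
    sizes = np.array([len(genome.chromosomes[c]) for c in chrom_names], dtype=float)
    probs = sizes / sizes.sum()
    reads, rows = [], []
    for _ in range(n):
        ci = int(rng.choice(len(chrom_names), p=probs))
        chrom = chrom_names[ci]
        start = int(rng.integers(0, int(sizes[ci]) - fragment_length))
        frag = genome.chromosomes[chrom][start:start + fragment_length]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            frag = reverse_complement(frag)
        reads.append(frag)
        rows.append((chrom, start, start + fragment_length, strand))
    origins = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
    return SelexPool(reads, origins)


@dataclass
class SelexResult:
    cycles: list[SelexPool]        # index 0 = input pool, 1..n = selected cycles
    motif_fraction: list[float]    # per cycle, fraction of reads with a site
    threshold: float               # log-odds score defining "contains a site"


def simulate_selex(pool: SelexPool, pwm: Pwm, cycles: int = 9,
                   reads_per_cycle: int = 2000, stringency: float = 1.0,
                   seed: int = 0, site_alpha: float = 0.001,
                   selection_alpha: float = 1e-4,
                   carryover: float = 0.3) -> SelexResult:
    """Iterated biased resampling of a pool by PWM affinity.

    Each cycle resamples ``reads_per_cycle`` reads with replacement, with
    retention weight carryover + (1 - carryover) * logistic(stringency *
    (best-window log-odds - midpoint)). The logistic midpoint is the score
    at occurrence p-value ``selection_alpha`` (a stringent wash retains only
    near-perfect sites preferentially); ``carryover`` models nonspecific
    retention, so one cycle barely shifts the pool while nine cycles enrich
    exponentially. stringency=0 is affinity-blind. The fraction of reads
    carrying a site at p <= ``site_alpha`` is recorded per cycle.
    """
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    if not 0 <= carryover < 1:
        raise ValueError("carryover must be in [0, 1)")
    rng = np.random.default_rng(seed)
    threshold = pwm.distribution().threshold(site_alpha)
    midpoint = pwm.distribution().threshold(selection_alpha)
    # a fragment's score never changes across cycles; score the input pool
    # once and track fragment indices through the resampling
    base_scores = best_scores(pwm, pool.reads)
    logistic = 1.0 / (1.0 + np.exp(-stringency * (base_scores - midpoint)))
    base_weights = carryover + (1.0 - carryover) * logistic
    has_site = base_scores >= threshold
    current_idx = np.arange(len(pool.reads))
    out_cycles = [pool]
    fractions = [float(has_site.mean())]
    for _ in range(cycles):
        weights = base_weights[current_idx]
        if weights.sum() <= 0:
            raise DegenerateSelectionError("all retention probabilities are zero")
        pick = rng.choice(len(current_idx), size=reads_per_cycle, replace=True,
                          p=weights / weights.sum())
        current_idx = current_idx[pick]
        reads = [pool.reads[i] for i in current_idx]
        origins = (pool.origins.iloc[current_idx].reset_index(drop=True)
                   if pool.origins is not None else None)
        out_cycles.append(SelexPool(reads, origins))
        fractions.append(float(has_site[current_idx].mean()))
    return SelexResult(out_cycles, fractions, threshold)


# --- ChIP-chip arrays ---------------------------------------------------------

def make_depletion_spec(genome: SyntheticGenome, genotypes: Sequence[str],
                        n_shared: int = 5, n_specific: int = 3,
                        patch_length: int = 3000, min_gap: int = 10_000,
                        meth_independent_fraction: float = 1.0,
                        seed: int = 0) -> pd.DataFrame:
    """Planted depletion patches: some shared by all genotypes, some exclusive.

    Patches are placed in the chromosome arms on the 250 bp tiling grid, at
    least ``min_gap`` bp apart. Exclusive patches of the first genotype are
    flagged methylation-independent with probability
    ``meth_independent_fraction`` (the methylome simulator gives those the
    "low" level in every genotype).
    """
    rng = np.random.default_rng(seed)
    chrom_names = list(genome.chromosomes)
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}

    def place_one(label: str) -> tuple[str, int, int]:
        for _ in range(2000):
            chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
            L = len(genome.chromosomes[chrom])
            start = int(rng.integers(0, (L - patch_length) // 250)) * 250
            end = start + patch_length
            if genome.in_pericentromere(chrom, start - min_gap, end + min_gap):
                continue
            if all(end + min_gap <= s or start >= e + min_gap for s, e in placed[chrom]):
                placed[chrom].append((start, end))
                return chrom, start, end
        raise PlacementError(f"could not place depletion patch {label}")

    rows = []
    for i in range(n_shared):
        chrom, start, end = place_one(f"shared_{i}")
        rows.append((chrom, start, end, ",".join(genotypes), False))
    for genotype in genotypes:
        meth_free = genotype == genotypes[0]
        for i in range(n_specific):
            chrom, start, end = place_one(f"{genotype}_{i}")
            indep = bool(meth_free and rng.random() < meth_independent_fraction)
            rows.append((chrom, start, end, genotype, indep))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "genotypes",
                                     "meth_independent"])
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def simulate_chip_arrays(genome: SyntheticGenome, genotypes: Sequence[str] = ("suvr5",),
                         depletion_spec: pd.DataFrame | None = None,
                         probe_spacing: int = 250, probe_length: int = 50,
                         het_level: float = 1.5, arm_level: float = 0.2,
                         effect: float = -2.0, noise_sd: float = 0.3,
                         seed: int = 0) -> tuple[dict[str, pd.DataFrame], TruthTable]:
    """Per-genotype probe tables (plus 'wildtype') with planted depletions.

    The latent H3K9me2 level is high over pericentromeres and TEs and low
    elsewhere; each genotype's planted patches add ``effect`` to its latent
    track. Probe log2(IP/input) = latent + N(0, noise_sd); input intensities
    are log-normal around 1000.
    """
    if probe_spacing <= 0:
        raise ValueError("probe_spacing must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if depletion_spec is None:
        depletion_spec = make_depletion_spec(genome, list(genotypes), seed=seed)
    rng = np.random.default_rng(seed)

    # per-chromosome probe grid and base latent level
    grids = {}
    for chrom, seq in genome.chromosomes.items():
        starts = np.arange(0, len(seq) - probe_length + 1, probe_spacing, dtype=int)
        mids = starts + probe_length // 2
        latent = np.full(len(starts), arm_level)
        for s, e in genome.pericentromeres.get(chrom, []):
            latent[(mids >= s) & (mids < e)] = het_level
        for te in genome.tes:
            if te.chrom == chrom:
                latent[(mids >= te.start) & (mids < te.end)] = het_level
        grids[chrom] = (starts, mids, latent)

    tables: dict[str, pd.DataFrame] = {}
    for genotype in ["wildtype", *genotypes]:
        rows = []
        for chrom, (starts, mids, latent) in grids.items():
            level = latent.copy()
            if genotype != "wildtype":
                mask = np.array([genotype in g.split(",")
                                 for g in depletion_spec["genotypes"]], dtype=bool)
                spec = depletion_spec.loc[mask]
                for _, patch in spec[spec["chrom"] == chrom].iterrows():
                    inside = (mids >= patch["start"]) & (mids < patch["end"])
                    level[inside] += effect
            inputs = 1000.0 * np.exp2(rng.normal(0, 0.3, len(starts)))
            noise = rng.normal(0, noise_sd, len(starts)) if noise_sd > 0 else 0.0
            ips = inputs * np.exp2(level + noise)
            for s, ip, inp in zip(starts, ips, inputs):
                rows.append((chrom, int(s), int(s) + probe_length, ip, inp))
        tables[genotype] = pd.DataFrame(rows, columns=_io.PROBE_COLUMNS)
    truth = TruthTable(depleted_regions=depletion_spec)
    return tables, truth


# --- methylome ----------------------------------------------------------------

DEFAULT_CONTEXT_LEVELS = {
    "het": {"CG": 0.85, "CHG": 0.45, "CHH": 0.08},
    "arm": {"CG": 0.15, "CHG": 0.03, "CHH": 0.015},
    "low": {"CG": 0.02, "CHG": 0.01, "CHH": 0.01},
}


def simulate_methylome(genome: SyntheticGenome,
                       context_levels: Mapping[str, Mapping[str, float]] | None = None,
                       depth: int = 20, seed: int = 0,
                       low_meth_patches: pd.DataFrame | None = None) -> Methylome:
    """Binomial per-cytosine counts with compartment- and context-specific levels.

    Compartments: 'het' (pericentromere or TE), 'arm' (everything else) and
    'low' for the supplied methylation-independent patches, which override
    either compartment in every genotype.
    """
    levels = DEFAULT_CONTEXT_LEVELS if context_levels is None else context_levels
    for comp in levels.values():
        if any(not 0 <= v <= 1 for v in comp.values()):
            raise ValueError("all methylation levels must be in [0, 1]")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    ctx = classify_contexts(genome.chromosomes)
    ctx = ctx[ctx["context"] != "incomplete"].reset_index(drop=True)

    level = np.empty(len(ctx))
    for chrom, cdf in ctx.groupby("chrom", sort=False):
        pos = cdf["pos"].to_numpy()
        comp = np.full(len(cdf), "arm", dtype=object)
        for s, e in genome.pericentromeres.get(chrom, []):
            comp[(pos >= s) & (pos < e)] = "het"
        for te in genome.tes:
            if te.chrom == chrom:
                comp[(pos >= te.start) & (pos < te.end)] = "het"
        if low_meth_patches is not None:
            for _, patch in low_meth_patches[low_meth_patches["chrom"] == chrom].iterrows():
                comp[(pos >= patch["start"]) & (pos < patch["end"])] = "low"
        ctx_sub = cdf["context"].to_numpy()
        sub = np.empty(len(cdf))
        for comp_name, by_ctx in levels.items():
            for ctx_name, value in by_ctx.items():
                sub[(comp == comp_name) & (ctx_sub == ctx_name)] = value
        level[cdf.index.to_numpy()] = sub
    calls = ctx.copy()
    calls["total_count"] = depth
    calls["meth_count"] = rng.binomial(depth, level)
    return Methylome(calls)


# --- RNA-seq ------------------------------------------------------------------

def make_de_spec(genes: Sequence[GeneModel], genotypes: Sequence[str],
                 n_shared: int = 20, n_first_only: int = 10, fold: float = 16.0,
                 seed: int = 0) -> dict[str, dict[str, float]]:
    """Epistatic DE design: one gene set planted at equal fold in every
    genotype, plus a set exclusive to the first genotype.

    Targets are drawn from the lowest-expressed third of genes — the
    silenced-in-wild-type design — which also keeps the composition shift of
    a closed library small, so planted folds survive RPKM normalization.
    """
    rng = np.random.default_rng(seed)
    order = np.argsort([g.baseline_expression for g in genes])
    low_third = order[: max(len(genes) // 3, n_shared + n_first_only)]
    ids = [g.id for g in genes]
    chosen = low_third[rng.choice(len(low_third), size=n_shared + n_first_only,
                                  replace=False)]
    shared = [ids[i] for i in chosen[:n_shared]]
    first_only = [ids[i] for i in chosen[n_shared:]]
    spec: dict[str, dict[str, float]] = {g: {gid: fold for gid in shared}
                                         for g in genotypes}
    for gid in first_only:
        spec[genotypes[0]][gid] = fold
    return spec


def simulate_rnaseq_counts(genes: Sequence[GeneModel], genotypes: Sequence[str],
                           de_spec: Mapping[str, Mapping[str, float]] | None = None,
                           library_size: int = 1_000_000, dispersion: float = 0.05,
                           seed: int = 0):
    """Negative-binomial counts around baseline x planted fold change.

    Variance is m + dispersion * m^2 (gamma-Poisson); dispersion=0 gives
    Poisson. Expected counts are scaled so each sample's expectation equals
    ``library_size``. Returns (CountsMatrix, TruthTable).
    """
    from .expression import CountsMatrix
    if not genes:
        raise ValueError("empty gene list")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    de_spec = de_spec or {}
    for spec in de_spec.values():
        if any(f <= 0 for f in spec.values()):
            raise ValueError("fold changes must be > 0")
    rng = np.random.default_rng(seed)
    ids = [g.id for g in genes]
    lengths = pd.Series({g.id: g.end - g.start for g in genes})
    baseline = np.array([g.baseline_expression for g in genes])
    data = {}
    truth_rows = []
    for genotype in genotypes:
        folds = np.ones(len(genes))
        for gid, fold in de_spec.get(genotype, {}).items():
            folds[ids.index(gid)] = fold
            truth_rows.append((genotype, gid, fold))
        mean = baseline * folds
        mean = mean / mean.sum() * library_size
        if dispersion > 0:
            lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
        else:
            lam = mean
        data[genotype] = rng.poisson(lam)
    counts = pd.DataFrame(data, index=pd.Index(ids, name="gene_id"))
    truth = TruthTable(de_genes=pd.DataFrame(truth_rows,
                                             columns=["genotype", "gene_id", "fold"]))
    return CountsMatrix(counts, lengths), truth
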