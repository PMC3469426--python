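"""Configuration-driven orchestration of the full analysis.

A single YAML config drives simulate -> motif -> chip -> methylation ->
expression -> integration in dependency order. One global seed fans out to
per-stage seeds by fixed offsets so any stage can be rerun in isolation;
reruns with the same config are byte-identical (no timestamps are written).
Every emitted file gets a ``.prov.json`` sidecar with its parameters, seed
and input digests.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import chip, expression, integration, io as _io, methylation, motif, synthetic

logger = logging.getLogger("suvrkit")

# fixed per-stage seed offsets (kept below 2**31 after fan-out)
STAGE_OFFSETS = {
    "genome": 1, "plant": 2, "selex": 3, "chip": 4,
    "meth_wt": 5, "meth_mut": 6, "rnaseq": 7, "em": 8,
}


@dataclass
class PipelineConfig:
    outdir: str = "suvrkit_run"
    seed: int = 0
    simulate: bool = True

    # genome
    n_chrom: int = 2
    chrom_length: int = 200_000
    gc: float = 0.36
    n_genes: int = 100
    n_tes: int = 60
    pericentromere_fraction: float = 0.2

    # motif / SELEX
    motif: str = synthetic.DEFAULT_MOTIF
    motif_gene_fraction: float = 0.4
    promoter_upstream: int = 1000
    selex_pool_size: int = 4000
    selex_cycles: int = 9
    selex_reads_per_cycle: int = 2000
    selex_stringency: float = 1.0
    discover_reads: int = 300
    discover_restarts: int = 3
    alpha_scan: float = 0.001

    # chip
    bin_size: int = 500
    step: int = 250
    z_cut: float = -3.0
    merge_gap: int = 2500
    min_bins: int = 3
    chip_noise_sd: float = 0.3
    chip_genotypes: tuple[str, ...] = ("suvr5", "kyp_suvh5_suvh6")
    n_shared_patches: int = 5
    n_specific_patches: int = 3

    # methylation
    meth_depth: int = 20
    meth_window: int = 50_000
    meth_step: int = 10_000

    # expression
    rnaseq_genotypes: tuple[str, ...] = ("suvr5", "ldl1_ldl2", "suvr5_ldl1_ldl2")
    library_size: int = 300_000
    dispersion: float = 0.05
    de_fold: float = 16.0
    n_shared_de: int = 20
    n_suvr5_only_de: int = 10
    de_alpha: float = 0.01
    min_log2_fold: float = 2.0

    # integration
    upstream_signal: int = 3000
    flank: int = 2000
    mapped_reads: int = 1500

    def validate(self) -> None:
        checks = [
            (self.z_cut < 0, "z_cut must be negative (only depletion is called)"),
            (0 < self.gc < 1, "gc must be in (0, 1)"),
            (0 < self.step <= self.bin_size, "require 0 < step <= bin_size"),
            (0 < self.alpha_scan <= 1, "alpha_scan must be in (0, 1]"),
            (0 < self.de_alpha <= 1, "de_alpha must be in (0, 1]"),
            (self.min_log2_fold >= 0, "min_log2_fold must be >= 0"),
            (self.merge_gap >= 0, "merge_gap must be >= 0"),
            (self.upstream_signal > 0, "upstream_signal must be > 0"),
            (self.promoter_upstream > 0, "promoter_upstream must be > 0"),
            (self.chip_noise_sd >= 0, "chip_noise_sd must be >= 0"),
            (self.selex_cycles >= 1, "selex_cycles must be >= 1"),
            (self.dispersion >= 0, "dispersion must be >= 0"),
            (0 <= self.motif_gene_fraction <= 1, "motif_gene_fraction must be in [0, 1]"),
        ]
        for ok, message in checks:
            if not ok:
                raise ValueError(f"invalid config: {message}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("chip_genotypes", "rnaseq_genotypes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        config = cls(**raw)
        config.validate()
        return config

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1009 + STAGE_OFFSETS[stage]) % (2 ** 31)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute every stage and write the report bundle; returns the summary."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    def save(name: str, writer, params: dict) -> Path:
        path = outdir / name
        writer(path)
        _io.write_provenance(path, params, config.seed)
        return path

    # --- simulate ------------------------------------------------------------
    logger.info("stage genome")
    genome = synthetic.make_genome(
        config.stage_seed("genome"), config.n_chrom, config.chrom_length, config.gc,
        config.n_genes, config.n_tes, config.pericentromere_fraction)
    genome, motif_truth = synthetic.plant_motif_sites(
        genome, config.motif, config.motif_gene_fraction, config.promoter_upstream,
        config.stage_seed("plant"))
    save("genome.fa", genome.write_fasta, {"n_chrom": config.n_chrom,
                                           "chrom_length": config.chrom_length})
    save("annotations.gff3", genome.write_gff3, {})

    # --- SELEX + motif -------------------------------------------------------
    logger.info("stage selex/motif")
    affinity = motif.consensus_pwm(config.motif, match=0.97)
    pool = synthetic.genomic_fragment_pool(genome, config.selex_pool_size,
                                           config.stage_seed("selex"))
    selex = synthetic.simulate_selex(pool, affinity, config.selex_cycles,
                                     config.selex_reads_per_cycle,
                                     config.selex_stringency,
                                     config.stage_seed("selex"))
    final_reads = selex.cycles[-1].reads[:config.discover_reads]
    discovered = motif.discover_motif(final_reads, width=len(config.motif),
                                      restarts=config.discover_restarts,
                                      seed=config.stage_seed("em"))
    save("discovered_motif.meme",
         lambda p: motif.write_meme(p, discovered.pwm), {"width": len(config.motif)})
    hits = motif.scan_genome(discovered.pwm, genome.chromosomes, config.alpha_scan)
    save("motif_hits.bed", lambda p: motif.hits_to_bed(hits, p),
         {"alpha": config.alpha_scan})

    # --- ChIP-chip -----------------------------------------------------------
    logger.info("stage chip")
    depletion_spec = synthetic.make_depletion_spec(
        genome, list(config.chip_genotypes), config.n_shared_patches,
        config.n_specific_patches, seed=config.stage_seed("chip"))
    tables, chip_truth = synthetic.simulate_chip_arrays(
        genome, config.chip_genotypes, depletion_spec,
        noise_sd=config.chip_noise_sd, seed=config.stage_seed("chip"))
    bins = chip.tile_genome(genome.chrom_sizes(), config.bin_size, config.step)
    tracks = {}
    for genotype, table in tables.items():
        table = chip.probe_log_ratio(table)
        table["log_ratio"] = chip.center_scale(table["log_ratio"])
        save(f"probes_{genotype}.tsv", lambda p, t=table: _io.write_probe_table(p, t),
             {"genotype": genotype, "noise_sd": config.chip_noise_sd})
        tracks[genotype] = chip.aggregate_bins(table, bins)
    regions = {}
    for genotype in config.chip_genotypes:
        reg = chip.call_decreased_regions(tracks[genotype], tracks["wildtype"],
                                          config.z_cut, config.merge_gap,
                                          config.min_bins, genotype)
        regions[genotype] = reg
        save(f"regions_{genotype}.bed",
             lambda p, r=reg: _io.write_bed(p, r.assign(name=genotype),
                                            score_col="mean_z", name_col="name",
                                            scale=1000),
             {"z_cut": config.z_cut, "merge_gap": config.merge_gap})
        save(f"regions_{genotype}.tsv", lambda p, r=reg: _io.write_tsv(p, r), {})
    te_profile = chip.metaprofile(tracks[config.chip_genotypes[0]], genome.tes_frame(),
                                  config.flank)
    save("te_metaprofile.tsv", lambda p: _io.write_tsv(p, te_profile),
         {"flank": config.flank})

    # --- methylation ---------------------------------------------------------
    logger.info("stage methylation")
    suvr5 = config.chip_genotypes[0]
    suvr5_patches = depletion_spec[depletion_spec["meth_independent"]]
    methylomes = {}
    for genotype, stage in (("wildtype", "meth_wt"), (suvr5, "meth_mut")):
        meth = synthetic.simulate_methylome(genome, depth=config.meth_depth,
                                            seed=config.stage_seed(stage),
                                            low_meth_patches=suvr5_patches)
        methylomes[genotype] = meth
        save(f"methylome_{genotype}.tsv", meth.to_tsv, {"depth": config.meth_depth})
        track = methylation.windowed_track(meth, genome.chrom_sizes(),
                                           config.meth_window, config.meth_step)
        save(f"meth_track_{genotype}.tsv", lambda p, t=track: _io.write_tsv(p, t),
             {"window": config.meth_window, "step": config.meth_step})
    suvr5_only = regions[suvr5]
    meth_profiles = {}
    if len(suvr5_only):
        for genotype, meth in methylomes.items():
            prof = methylation.meth_metaprofile(meth, suvr5_only, config.flank)
            meth_profiles[genotype] = prof
            for ctx, df in prof.items():
                save(f"meth_metaprofile_{genotype}_{ctx}.tsv",
                     lambda p, d=df: _io.write_tsv(p, d), {"context": ctx})

    # --- expression ----------------------------------------------------------
    logger.info("stage expression")
    de_spec = synthetic.make_de_spec(genome.genes, list(config.rnaseq_genotypes),
                                     config.n_shared_de, config.n_suvr5_only_de,
                                     config.de_fold, config.stage_seed("rnaseq"))
    counts, de_truth = synthetic.simulate_rnaseq_counts(
        genome.genes, ["wildtype", *config.rnaseq_genotypes], de_spec,
        config.library_size, config.dispersion, config.stage_seed("rnaseq"))
    save("counts.tsv", counts.to_tsv, {"library_size": config.library_size})
    de_results = {}
    for genotype in config.rnaseq_genotypes:
        res = expression.call_differential_genes(counts, genotype, "wildtype",
                                                 config.min_log2_fold, config.de_alpha)
        de_results[genotype] = res
        save(f"de_{genotype}.tsv", lambda p, r=res: _io.write_tsv(p, r),
             {"alpha": config.de_alpha, "min_log2_fold": config.min_log2_fold})
    called_sets = {g: set(r[r["called"]]["gene_id"]) for g, r in de_results.items()}
    shared_de = called_sets[config.rnaseq_genotypes[0]] & called_sets[config.rnaseq_genotypes[1]]
    rpkm_tbl = counts.rpkm()
    epistasis = None
    if shared_de:
        _, epistasis = expression.geneset_rpkm_summary(
            rpkm_tbl, sorted(shared_de), wildtype="wildtype",
            single=config.rnaseq_genotypes[0], combined=config.rnaseq_genotypes[-1])

    # --- integration ---------------------------------------------------------
    logger.info("stage integration")
    mapped, map_stats = integration.map_reads_exact(
        selex.cycles[-1].reads[:config.mapped_reads], genome.chromosomes)
    genes_df = genome.genes_frame()
    signal_genes = integration.genes_with_upstream_signal(
        genes_df, mapped, config.promoter_upstream, genome.chrom_sizes())
    venn = integration.interval_overlap_venn(regions[config.chip_genotypes[0]],
                                             regions[config.chip_genotypes[1]])
    # genes overlapping decreased regions, and their promoter-signal fraction
    body_overlap = set()
    trees = integration.merge_interval_set(regions[suvr5])
    for _, g in genes_df.iterrows():
        sub = trees[(trees["chrom"] == g["chrom"]) & (trees["start"] < g["end"])
                    & (trees["end"] > g["start"])]
        if len(sub):
            body_overlap.add(g["id"])
    pct_decreased_with_signal = (100.0 * len(body_overlap & signal_genes) / len(body_overlap)
                                 if body_overlap else None)
    overall_signal = integration.interval_overlap_venn(regions[suvr5], mapped)
    pct_regions_with_signal = (100.0 * overall_signal.shared_a / overall_signal.a_total
                               if overall_signal.a_total else None)
    # "contains the motif" is a literal word match, not a p<=alpha hit:
    # at alpha_scan the near-match density saturates every +/-flank window
    exact_rows = []
    for chrom, seq in genome.chromosomes.items():
        start = seq.find(discovered.consensus)
        while start >= 0:
            exact_rows.append((chrom, start))
            start = seq.find(discovered.consensus, start + 1)
    exact_hits = pd.DataFrame(exact_rows, columns=["chrom", "start"])
    motif_fraction = None
    if len(genome.tes) and len(exact_hits):
        motif_fraction, _ = integration.fraction_features_with_motif(
            genome.tes_frame(), exact_hits, config.flank)

    summary = {
        "motif": {
            "discovered_consensus": discovered.consensus,
            "palindromic": discovered.consensus == motif.reverse_complement(
                discovered.consensus),
            "n_genome_hits": int(len(hits)),
            "selex_motif_fraction_by_cycle": [round(f, 4) for f in selex.motif_fraction],
        },
        "chip": {
            "n_regions": {g: int(len(r)) for g, r in regions.items()},
            "venn": {"a_total": venn.a_total, "b_total": venn.b_total,
                     "shared_a": venn.shared_a, "shared_b": venn.shared_b,
                     "a_only": venn.a_only, "b_only": venn.b_only,
                     "pct_suvr5_specific": (100.0 * venn.a_only / venn.a_total
                                            if venn.a_total else None)},
        },
        "integration": {
            "mapping": map_stats,
            "n_genes_with_promoter_signal": len(signal_genes),
            "pct_decreased_genes_with_promoter_signal": pct_decreased_with_signal,
            "pct_regions_with_gselex_signal": pct_regions_with_signal,
            "pct_tes_with_motif": (100.0 * motif_fraction
                                   if motif_fraction is not None else None),
        },
        "expression": {
            "n_called": {g: int(r["called"].sum()) for g, r in de_results.items()},
            "n_shared_called": len(shared_de),
            "no_calls": all(r["called"].sum() == 0 for r in de_results.values()),
            "epistasis_descriptor": epistasis,
        },
        "truth": {
            "n_planted_motif_sites": int(len(motif_truth.motif_sites)),
            "n_planted_patches": int(len(depletion_spec)),
            "n_planted_de": {g: len(s) for g, s in de_spec.items()},
        },
    }
    write_reports(summary, outdir)
    for truth in (motif_truth, chip_truth, de_truth):
        truth.write(outdir)
    logger.info("pipeline finished in %.1f s", time.time() - t0)
    return summary


def write_reports(summary: dict, outdir: str | Path) -> Path:
    """Write the headline-statistics summary JSON (schema-checked)."""
    required = {"motif", "chip", "integration", "expression"}
    missing = required - set(summary)
    if missing:
        # partial results: keep explicit nulls rather than dropping sections
        for key in missing:
            summary[key] = None
    path = Path(outdir) / "summary.json"
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
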