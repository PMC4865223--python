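"""End-to-end orchestration: simulate, design, call, filter, map, validate.

Runs the full genotyping-by-capture analysis on a synthetic study and
writes every artifact with a provenance header (package version, master
seed, configuration hash), so that re-running an identical configuration
reproduces identical outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from capmap import __version__, io
from capmap.baits import bait_counts_by_contig, design_all, select_targets
from capmap.calling import call_genotype_table, classify_table, discover_bonus_snps
from capmap.filtering import FilterResult, FilterThresholds, apply_filters
from capmap.mapping import AnnealParams, GeneticMapResult, build_genetic_map
from capmap.simulate import (
    WHEAT_CHROMOSOMES,
    CoverageModel,
    Reference,
    ReadcountSet,
    SimTruth,
    build_map_spec,
    default_locus_table,
    generate_reference,
    make_putative_positions,
    simulate_capture_readcounts,
    simulate_ril_population,
)
from capmap.summary import aggregate_chromosome_summary, summarize_map
from capmap.validation import (
    assignment_consistency,
    detect_translocation_blocks,
    polyfit_outliers,
    spearman_by_chromosome,
)

logger = logging.getLogger("capmap.pipeline")


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; the seed is mandatory for simulation."""

    seed: int | None = None
    outdir: str | None = None
    # synthetic study scale
    n_contigs: int = 700
    n_individuals: int = 135
    generations: int = 6
    n_chromosomes: int = 14
    chr_length_cM: float = 200.0
    cm_per_mb: float = 1.0
    # reference composition
    homeolog_fraction: float = 0.23
    microsat_fraction: float = 0.003
    epo_fraction: float = 0.30
    epo_monomorphic_fraction: float = 0.41
    second_snp_fraction: float = 0.15
    # coverage model
    coverage: CoverageModel = field(default_factory=CoverageModel)
    # filters
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    # linkage mapping
    lod_min: float = 7.0
    rf_max: float = 0.14
    min_shared: int = 30
    min_group_size: int = 3
    anneal: AnnealParams = field(default_factory=AnnealParams)
    # putative-assignment noise
    putative_swap_prob: float = 0.10
    putative_other_prob: float = 0.02
    putative_missing_prob: float = 0.30

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "coverage" in data and isinstance(data["coverage"], dict):
            data["coverage"] = CoverageModel(**data["coverage"])
        if "thresholds" in data and isinstance(data["thresholds"], dict):
            data["thresholds"] = FilterThresholds(**data["thresholds"])
        if "anneal" in data and isinstance(data["anneal"], dict):
            data["anneal"] = AnnealParams(**data["anneal"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            return cls.from_dict(yaml.safe_load(handle) or {})

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output paths excluded)."""
        payload = self.to_dict()
        payload.pop("outdir", None)
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]

    def provenance(self) -> dict:
        return {"capmap_version": __version__, "seed": self.seed, "config_hash": self.config_hash()}


@dataclass
class PipelineResult:
    config: PipelineConfig
    reference: Reference
    truth: SimTruth
    readcounts: ReadcountSet
    baits: list
    design_report: pd.DataFrame
    genotypes: pd.DataFrame  # targeted loci x individuals
    classifications: pd.DataFrame
    bonus_records: pd.DataFrame
    bonus_genotypes: pd.DataFrame
    filtering: FilterResult
    putative: pd.DataFrame  # marker-level putative positions
    map_result: GeneticMapResult
    map_summary: pd.DataFrame
    validation_report: pd.DataFrame
    translocation_blocks: pd.DataFrame
    consistency: dict


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage in order; any failure aborts naming the stage."""
    if config.seed is None:
        raise ValueError("a master seed is required when simulation is enabled")
    seeds = _stage_seeds(config.seed)
    stage = "setup"
    try:
        stage = "simulate-reference"
        logger.info("stage %s", stage)
        reference = generate_reference(
            config.n_contigs,
            seed=seeds[0],
            homeolog_fraction=config.homeolog_fraction,
            microsat_fraction=config.microsat_fraction,
            epo_fraction=config.epo_fraction,
            epo_monomorphic_fraction=config.epo_monomorphic_fraction,
            second_snp_fraction=config.second_snp_fraction,
        )
        map_spec = build_map_spec(
            reference,
            chromosomes=WHEAT_CHROMOSOMES[: config.n_chromosomes],
            chr_length_cM=config.chr_length_cM,
            cm_per_mb=config.cm_per_mb,
            seed=seeds[1],
        )

        stage = "design-baits"
        logger.info("stage %s", stage)
        contig_lengths = {name: len(seq) for name, seq in reference.contigs.items()}
        targets, selection_report = select_targets(reference.snps, reference.exons, contig_lengths)
        baits, design_report = design_all(targets, reference.contigs)
        bait_counts = bait_counts_by_contig(targets)

        stage = "simulate-population"
        logger.info("stage %s", stage)
        truth = simulate_ril_population(
            map_spec, config.n_individuals, config.generations, seed=seeds[2]
        )

        stage = "simulate-readcounts"
        logger.info("stage %s", stage)
        locus_table = default_locus_table(truth, reference)
        designable = set(bait_counts)
        locus_table = locus_table[
            ~locus_table["is_targeted"] | locus_table["contig"].isin(designable)
        ].reset_index(drop=True)
        readcounts = simulate_capture_readcounts(
            truth,
            config.coverage,
            seed=seeds[3],
            bait_counts=bait_counts,
            locus_table=locus_table,
            sink_contigs=reference.microsat_contigs,
        )

        stage = "call-genotypes"
        logger.info("stage %s", stage)
        counts = readcounts.counts
        targeted_counts = counts[counts["is_targeted"]]
        genotypes = call_genotype_table(targeted_counts, min_depth=config.thresholds.depth_targeted)
        classifications = classify_table(genotypes)
        bonus_records, bonus_genotypes = discover_bonus_snps(
            counts,
            min_depth=config.thresholds.depth_bonus,
            targeted_contigs=set(bait_counts),
        )

        stage = "filter"
        logger.info("stage %s", stage)
        targeted_ds = int((reference.snps["origin"] == "DS").sum())
        filtering = apply_filters(
            genotypes,
            classifications,
            config.thresholds,
            bonus_genotypes=bonus_genotypes,
            bonus_records=bonus_records,
            targeted_ds=targeted_ds,
        )

        stage = "map"
        logger.info("stage %s", stage)
        clean = pd.concat(
            [genotypes.loc[filtering.er_clean], bonus_genotypes.loc[filtering.bonus_deduped]]
        )
        putative_contigs = make_putative_positions(
            map_spec,
            swap_prob=config.putative_swap_prob,
            other_prob=config.putative_other_prob,
            missing_prob=config.putative_missing_prob,
            seed=seeds[4],
        )
        by_contig = putative_contigs.set_index("contig")
        marker_contig = pd.Series(
            {m: m.rsplit("@", 1)[0] for m in clean.index}, name="contig"
        )
        putative = pd.DataFrame({"marker": marker_contig.index, "contig": marker_contig.to_numpy()})
        putative = putative.join(by_contig, on="contig").dropna(subset=["putative_chromosome"])
        putative_chrom = dict(zip(putative["marker"], putative["putative_chromosome"]))
        orient_by = dict(zip(putative["marker"], putative["putative_cM"]))
        map_result = build_genetic_map(
            clean,
            putative_chrom,
            orient_by,
            lod_min=config.lod_min,
            rf_max=config.rf_max,
            min_shared=config.min_shared,
            min_group_size=config.min_group_size,
            seed=seeds[5],
            anneal=config.anneal,
        )

        stage = "validate"
        logger.info("stage %s", stage)
        genetic_map = map_result.map
        map_summary = aggregate_chromosome_summary(summarize_map(genetic_map))
        rho_phys = spearman_by_chromosome(genetic_map, putative, "putative_bp")
        rho_gen = spearman_by_chromosome(genetic_map, putative, "putative_cM")
        validation_rows = []
        merged = genetic_map.merge(putative, on="marker", how="left")
        for chrom, sub in merged.groupby("chromosome"):
            usable = sub.dropna(subset=["putative_bp"])
            same = usable[usable["putative_chromosome"] == chrom]
            row = {
                "chromosome": chrom,
                "n_markers": len(sub),
                "spearman_phys": float(
                    rho_phys.set_index("chromosome").loc[chrom, "spearman_rho"]
                ),
                "spearman_gen": float(rho_gen.set_index("chromosome").loc[chrom, "spearman_rho"]),
                "adjusted_r2": np.nan,
                "n_outliers": np.nan,
            }
            if len(same) >= 5:
                fit = polyfit_outliers(same["position_cM"], same["putative_bp"])
                row["adjusted_r2"] = fit.adjusted_r2
                row["n_outliers"] = int(fit.outlier.sum())
            validation_rows.append(row)
        validation_report = pd.DataFrame(validation_rows)
        blocks = detect_translocation_blocks(genetic_map, putative)
        consistency = assignment_consistency(map_result.groups)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    result = PipelineResult(
        config=config,
        reference=reference,
        truth=truth,
        readcounts=readcounts,
        baits=baits,
        design_report=pd.concat(
            [selection_report.assign(table="selection"), design_report.assign(table="design")]
        ),
        genotypes=genotypes,
        classifications=classifications,
        bonus_records=bonus_records,
        bonus_genotypes=bonus_genotypes,
        filtering=filtering,
        putative=putative,
        map_result=map_result,
        map_summary=map_summary,
        validation_report=validation_report,
        translocation_blocks=blocks,
        consistency=consistency,
    )
    if config.outdir is not None:
        write_outputs(result)
    return result


def write_outputs(result: PipelineResult) -> dict[str, Path]:
    """Write every pipeline artifact under the configured output directory."""
    config = result.config
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = config.provenance()
    paths: dict[str, Path] = {}

    paths["reference_fasta"] = outdir / "reference.fasta"
    io.write_fasta(result.reference.contigs, paths["reference_fasta"])
    paths["baits_fasta"] = outdir / "baits.fasta"
    io.write_fasta({b.name: b.sequence for b in result.baits}, paths["baits_fasta"])

    tables = {
        "exons": result.reference.exons,
        "snps": result.reference.snps,
        "truth_map": result.truth.map_spec.loci,
        "truth_genotypes": result.truth.genotypes.reset_index(),
        "readcounts": result.readcounts.counts,
        "sink_reads": result.readcounts.sink,
        "design_report": result.design_report,
        "genotypes": result.genotypes.reset_index(),
        "locus_classification": result.classifications.reset_index(),
        "bonus_records": result.bonus_records.reset_index(),
        "accounting": result.filtering.accounting.to_frame(),
        "putative_positions": result.putative,
        "map": result.map_result.map,
        "linkage_groups": result.map_result.groups,
        "map_summary": result.map_summary,
        "validation_report": result.validation_report,
        "translocation_blocks": result.translocation_blocks,
    }
    for name, frame in tables.items():
        paths[name] = outdir / f"{name}.csv"
        io.write_table(frame, paths[name], meta=meta)
    return paths
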