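"""End-to-end pipeline driver and configuration.

``run_all`` executes simulate -> cluster -> pangenome -> phylo ->
phenotype -> gtm against a work directory, writing every stage's outputs
plus a manifest recording parameters, seeds and SHA-256 checksums of the
produced files.  Outputs are deterministic: rerunning with the same
configuration gives byte-identical files and manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as pio
from .clustering import (
    all_vs_all_identity,
    build_graph,
    extract_single_copy,
    filter_similarities,
    mcl_cluster,
)
from .gtm import (
    DEFAULT_EXCLUSION_KEYWORDS,
    build_genotype_matrix,
    collapse_patterns,
    family_annotations,
    match_all,
    report_hits,
)
from .pangenome import (
    accumulation_curves,
    hierarchical_heatmap_export,
    partition_families,
    presence_absence,
)
from .phenotype import build_phenotype_matrix, select_differential
from .phylogeny import build_supertree
from .simulate import (
    CONTROL_CARBOHYDRATE,
    SimulationConfig,
    simulate_growth_curves,
    simulate_pangenome,
)

__all__ = ["PipelineConfig", "run_all", "load_config"]

logger = logging.getLogger("pangtm")


@dataclass
class PipelineConfig:
    """All pipeline parameters with their standard defaults.

    Clustering defaults mirror the family-definition constants (50%
    identity, e-value 1e-4, MCL inflation 2.5); phenotyping reads the
    12-h OD; matching uses the strictly-greater-than-95% hit rule.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    min_identity: float = 50.0
    max_evalue: float = 1e-4
    inflation: float = 2.5
    n_permutations: int = 100
    phenotype_time_h: float = 12.0
    control_carbohydrate: str = CONTROL_CARBOHYDRATE
    exclusion_keywords: tuple[str, ...] = DEFAULT_EXCLUSION_KEYWORDS
    match_threshold: float = 95.0
    indeterminate_policy: str = "as_zero"
    consensus_threshold: float = 0.5
    extended_majority: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_identity <= 100.0:
            raise ValueError("min_identity must be in [0, 100]")
        if self.max_evalue < 0:
            raise ValueError("max_evalue must be non-negative")
        if self.inflation <= 1.0:
            raise ValueError("inflation must be > 1")
        if not 0.0 < self.match_threshold <= 100.0:
            raise ValueError("match_threshold must be in (0, 100]")
        if self.indeterminate_policy not in ("as_zero", "strict"):
            raise ValueError("indeterminate_policy must be 'as_zero' or 'strict'")


_SIM_FIELDS = {f.name for f in dataclasses.fields(SimulationConfig)}
_PIPE_FIELDS = {f.name for f in dataclasses.fields(PipelineConfig)} - {"simulation"}


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML configuration; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    sim_raw = raw.pop("simulation", {}) or {}
    unknown = set(raw) - _PIPE_FIELDS
    if unknown:
        raise ValueError(f"{path}: unknown configuration keys {sorted(unknown)}")
    unknown_sim = set(sim_raw) - _SIM_FIELDS
    if unknown_sim:
        raise ValueError(f"{path}: unknown simulation keys {sorted(unknown_sim)}")
    for tup_key in ("occurrence_prob_range", "unique_per_strain_range",
                    "cluster_size_range", "growth_od12_range",
                    "nogrowth_od12_range"):
        if tup_key in sim_raw and isinstance(sim_raw[tup_key], list):
            sim_raw[tup_key] = tuple(sim_raw[tup_key])
    if "exclusion_keywords" in raw and isinstance(raw["exclusion_keywords"], list):
        raw["exclusion_keywords"] = tuple(raw["exclusion_keywords"])
    sim = SimulationConfig(**sim_raw)
    cfg = PipelineConfig(simulation=sim, **raw)
    if "seed" in raw and "seed" not in sim_raw:
        # a top-level seed propagates to the simulator unless overridden
        cfg = dataclasses.replace(
            cfg, simulation=dataclasses.replace(sim, seed=cfg.seed)
        )
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_payload(config: PipelineConfig) -> dict:
    payload = dataclasses.asdict(config)
    payload["exclusion_keywords"] = list(config.exclusion_keywords)
    return payload


def run_all(config: PipelineConfig, workdir: str | Path) -> dict:
    """Run the whole pipeline under ``workdir``; returns the manifest.

    Stage outputs land in per-stage subdirectories; the manifest JSON
    records the configuration and a checksum for every file written.  Any
    stage failure aborts with the stage name; already-written outputs are
    left in place for inspection.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"

    def emit(path: Path) -> Path:
        written.append(path)
        return path

    try:
        # ------------------------------------------------- simulate
        stage = "simulate"
        logger.info("stage %s", stage)
        sim_dir = workdir / "simulate"
        sim_dir.mkdir(exist_ok=True)
        sim = config.simulation
        genomes, annotations, truth = simulate_pangenome(sim)
        for strain in sim.taxa:
            pio.write_fasta(
                {g: genomes[strain][g] for g in sorted(genomes[strain])},
                emit(sim_dir / f"{strain}.faa"),
            )
        pio.write_annotations(annotations, emit(sim_dir / "annotations.tsv"))
        curves = simulate_growth_curves(truth, sim)
        pio.write_growth_curves(curves, emit(sim_dir / "growth_curves.csv"))
        (sim_dir / "truth.json").write_text(truth.to_json() + "\n")
        emit(sim_dir / "truth.json")

        # ------------------------------------------------- cluster
        stage = "cluster"
        logger.info("stage %s", stage)
        clu_dir = workdir / "cluster"
        clu_dir.mkdir(exist_ok=True)
        sequences = {
            gene: seq for strain in sim.taxa for gene, seq in genomes[strain].items()
        }
        records = all_vs_all_identity(sequences)
        passing = filter_similarities(
            records, min_identity=config.min_identity, max_evalue=config.max_evalue
        )
        graph = build_graph(passing, sorted(sequences))
        families = mcl_cluster(graph, inflation=config.inflation)
        pio.write_families(families, emit(clu_dir / "families.tsv"))
        pio.write_json(
            {
                "n_genes": len(sequences),
                "n_records": len(records),
                "n_passing": len(passing),
                "n_families": len(families),
                "min_identity": config.min_identity,
                "max_evalue": config.max_evalue,
                "inflation": config.inflation,
            },
            emit(clu_dir / "provenance.json"),
        )

        # ------------------------------------------------- pangenome
        stage = "pangenome"
        logger.info("stage %s", stage)
        pan_dir = workdir / "pangenome"
        pan_dir.mkdir(exist_ok=True)
        strains = list(sim.strains)  # ingroup only
        matrix = presence_absence(families, strains)
        pio.write_matrix(matrix, emit(pan_dir / "presence_absence.tsv"))
        part = partition_families(matrix)
        pio.write_json(
            {
                "n_core": part.n_core,
                "n_dispensable_shared": part.n_dispensable,
                "n_unique": part.n_unique,
                "n_variable": len(part.variable),
                "core_fraction_pct": part.core_fraction_pct(),
                "unique_per_genome": dict(sorted(part.unique_per_genome().items())),
            },
            emit(pan_dir / "partition.json"),
        )
        curve = accumulation_curves(
            matrix, n_permutations=config.n_permutations, seed=config.seed
        )
        curve.to_frame().to_csv(
            emit(pan_dir / "accumulation.csv"), index=False, lineterminator="\n"
        )
        pio.write_json(
            {
                "fitted_pan": list(curve.fitted_pan) if curve.fitted_pan else None,
                "fitted_core": list(curve.fitted_core) if curve.fitted_core else None,
                "n_permutations": curve.n_permutations,
                "exhaustive": curve.exhaustive,
            },
            emit(pan_dir / "curve_fits.json"),
        )
        ordered, _, dendro = hierarchical_heatmap_export(matrix)
        pio.write_matrix(ordered, emit(pan_dir / "presence_absence_ordered.tsv"))
        (pan_dir / "genome_dendrogram.nwk").write_text(dendro + "\n")
        emit(pan_dir / "genome_dendrogram.nwk")

        # ------------------------------------------------- phylo
        stage = "phylo"
        logger.info("stage %s", stage)
        phy_dir = workdir / "phylo"
        phy_dir.mkdir(exist_ok=True)
        taxa = list(sim.taxa)
        single_copy = extract_single_copy(families, taxa)
        alignments = {
            fid: {
                genome: sequences[by_gen[genome][0]]
                for genome, by_gen in [(g, single_copy.families[fid]) for g in taxa]
            }
            for fid in single_copy.families
        }
        supertree, fam_trees, freqs = build_supertree(
            alignments,
            outgroup=sim.outgroup,
            threshold=config.consensus_threshold,
            extended=config.extended_majority,
        )
        (phy_dir / "supertree.nwk").write_text(
            supertree.as_string(schema="newick", suppress_rooting=True)
        )
        emit(phy_dir / "supertree.nwk")
        freqs.to_csv(emit(phy_dir / "bipartitions.tsv"), sep="\t", index=False,
                     lineterminator="\n")
        pio.write_json(
            {"n_single_copy_families": len(single_copy), "n_trees": len(fam_trees)},
            emit(phy_dir / "phylo_summary.json"),
        )

        # ------------------------------------------------- phenotype
        stage = "phenotype"
        logger.info("stage %s", stage)
        phe_dir = workdir / "phenotype"
        phe_dir.mkdir(exist_ok=True)
        pheno = build_phenotype_matrix(
            curves, time_h=config.phenotype_time_h,
            control=config.control_carbohydrate,
        )
        pio.write_phenotype_matrix(pheno.calls, emit(phe_dir / "phenotype_matrix.tsv"))
        pio.write_json(
            {
                "differential": select_differential(pheno),
                "controls": sorted(pheno.controls),
                "n_indeterminate": pheno.n_indeterminate(),
            },
            emit(phe_dir / "phenotype_summary.json"),
        )

        # ------------------------------------------------- gtm
        stage = "gtm"
        logger.info("stage %s", stage)
        gtm_dir = workdir / "gtm"
        gtm_dir.mkdir(exist_ok=True)
        fam_ann = family_annotations(families.families, annotations)
        filtered, dropped = build_genotype_matrix(
            matrix, fam_ann, exclusion_keywords=config.exclusion_keywords
        )
        patterns = collapse_patterns(filtered, annotations=fam_ann)
        pio.write_matrix(patterns.patterns, emit(gtm_dir / "genotype_matrix.tsv"))
        result = match_all(
            patterns, pheno, policy=config.indeterminate_policy
        )
        pio.write_matrix(result.matches, emit(gtm_dir / "match_heatmap.tsv"))
        hits, partial = report_hits(result, patterns, threshold=config.match_threshold)
        pio.write_json(
            {
                "threshold_pct": config.match_threshold,
                "dropped": {k: len(v) for k, v in dropped.items()},
                "hits": [dataclasses.asdict(h) for h in hits],
                "partial_matches": [dataclasses.asdict(h) for h in partial[:20]],
            },
            emit(gtm_dir / "hits.json"),
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    manifest = {
        "config": _config_payload(config),
        "files": {
            str(p.relative_to(workdir)): _sha256(p) for p in sorted(written)
        },
    }
    pio.write_json(manifest, workdir / "manifest.json")
    return manifest
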