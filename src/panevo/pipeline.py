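"""End-to-end pipeline orchestration with fixed seeds and a run manifest.

Stages: cluster -> pan matrix -> rarefy/fit -> partition -> core entropy +
Ka/Ks -> optional feature correlations -> optional interolog transfer.
Every intermediate artifact is written to the output directory and recorded
in ``manifest.json`` with a checksum, so a rerun with the same config and
seed reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import ProteinRecord, build_pan_matrix, greedy_cluster, partition_pan
from .interolog import HomologyFilter, predict_interologs, summarize_network
from .io import read_blast_tab, read_fasta, read_tsv, write_tsv
from .rarefaction import fit_openness, rarefy
from .selection import (
    codon_align,
    compare_core_vs_chromosome,
    estimate_relative_entropy,
    family_omega,
    observed_codon_frequencies,
)
from .stats import correlate_with_genome_size

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending record."""


@dataclass
class PipelineConfig:
    """All pipeline inputs, thresholds and seeds in one serializable object.

    ``genomes`` maps genome id to its protein (``.faa``) and CDS (``.fna``)
    FASTA paths.  Defaults carry the analysis conventions: 50% clustering
    identity, 30 rarefaction iterations, alpha = 0.001 for correlations,
    and the interolog homology thresholds.
    """

    genomes: dict[str, dict[str, str]] = field(default_factory=dict)
    outdir: str = "panevo_run"
    clustering_threshold: float = 0.50
    rarefaction_iterations: int = 30
    entropy_null_model: str = "positional_nucleotide"
    kaks_max_families: int | None = None
    correlation_alpha: float = 0.001
    feature_table: str | None = None
    microbe_hits: str | None = None
    host_hits: str | None = None
    template_edges: str | None = None
    interolog_evalue_max: float = 1e-10
    interolog_identity_min: float = 30.0
    interolog_query_cov_min: float = 60.0
    interolog_template_cov_min: float = 90.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.clustering_threshold <= 1.0:
            raise ValueError("clustering_threshold must lie in (0, 1]")
        if self.rarefaction_iterations < 1:
            raise ValueError("rarefaction_iterations must be >= 1")
        if not 0.0 < self.correlation_alpha < 1.0:
            raise ValueError("correlation_alpha must lie in (0, 1)")

    def stage_seed(self, stage: str) -> int:
        """Per-stage seed via a fixed derivation from the global seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; returns the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "panevo_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "stages": {},
        "files": {},
    }

    def record(name: str, path: Path) -> None:
        manifest["files"][name] = {"path": str(path), "sha256": _sha256(path), "bytes": path.stat().st_size}

    # -- validation -------------------------------------------------------
    if not config.genomes:
        raise PipelineError("validation: no genomes configured")
    proteins: list[ProteinRecord] = []
    cds_by_gene: dict[str, str] = {}
    cds_by_genome: dict[str, list[tuple[str, str]]] = {}
    for genome_id, paths in config.genomes.items():
        for key in ("protein", "cds"):
            if key not in paths or not Path(paths[key]).exists():
                raise PipelineError(f"validation: genome {genome_id!r}: missing {key} FASTA")
        for header, seq in read_fasta(paths["protein"]):
            gene_id = header.split()[0]
            proteins.append(ProteinRecord(gene_id, genome_id, seq))
        cds_by_genome[genome_id] = []
        for header, seq in read_fasta(paths["cds"]):
            gene_id = header.split()[0]
            cds_by_gene[gene_id] = seq
            cds_by_genome[genome_id].append((gene_id, seq))
    genome_of = {p.gene_id: p.genome_id for p in proteins}
    missing_cds = [p.gene_id for p in proteins if p.gene_id not in cds_by_gene]
    if missing_cds:
        raise PipelineError(f"validation: protein gene(s) without CDS: {missing_cds[:5]}")
    logger.info("validated %d genomes, %d proteins", len(config.genomes), len(proteins))

    # -- clustering -------------------------------------------------------
    try:
        assignment = greedy_cluster(proteins, threshold=config.clustering_threshold)
    except Exception as exc:
        raise PipelineError(f"clustering: {exc}") from exc
    fam_table = pd.DataFrame(
        {
            "family_id": list(assignment.families),
            "centroid": [assignment.centroids[f] for f in assignment.families],
            "members": [",".join(m) for m in assignment.families.values()],
        }
    )
    write_tsv(outdir / "families.tsv", fam_table)
    record("families.tsv", outdir / "families.tsv")
    manifest["stages"]["clustering"] = {"n_proteins": len(proteins), "n_families": len(assignment)}

    matrix = build_pan_matrix(assignment, genome_of, genome_ids=list(config.genomes))
    matrix.rename_axis("family_id").reset_index().pipe(lambda t: write_tsv(outdir / "pan_matrix.tsv", t))
    record("pan_matrix.tsv", outdir / "pan_matrix.tsv")

    # -- rarefaction and openness ----------------------------------------
    result = rarefy(matrix, iterations=config.rarefaction_iterations, seed=config.stage_seed("rarefy"))
    write_tsv(outdir / "rarefaction_curves.tsv", result.to_frame())
    record("rarefaction_curves.tsv", outdir / "rarefaction_curves.tsv")
    fit = fit_openness(result)
    fit.write_json(outdir / "openness_fit.json")
    record("openness_fit.json", outdir / "openness_fit.json")
    core, accessory, unique = partition_pan(matrix)
    manifest["stages"]["pangenome"] = {
        "n_families": int(matrix.shape[0]),
        "n_core": len(core),
        "n_accessory": len(accessory),
        "n_unique": len(unique),
        "verdict": fit.verdict,
        "gamma": fit.gamma,
    }

    # -- core entropy -----------------------------------------------------
    core_set = set(core)
    dkl_core, dkl_chrom = {}, {}
    for genome_id, gene_cds in cds_by_genome.items():
        core_cds = [(g, s) for g, s in gene_cds if assignment.gene_to_family.get(g) in core_set]
        if not core_cds:
            raise PipelineError(f"entropy: genome {genome_id!r} has no core genes")
        obs_core = observed_codon_frequencies(core_cds, label="core")
        obs_chrom = observed_codon_frequencies(gene_cds, label="chromosome")
        dkl_core[genome_id] = estimate_relative_entropy(obs_core, config.entropy_null_model)
        dkl_chrom[genome_id] = estimate_relative_entropy(obs_chrom, config.entropy_null_model)
    entropy = compare_core_vs_chromosome(dkl_core, dkl_chrom)
    entropy_table = pd.DataFrame(
        {
            "genome_id": list(dkl_core),
            "dkl_core_bits": [dkl_core[g] for g in dkl_core],
            "dkl_chromosome_bits": [dkl_chrom[g] for g in dkl_core],
        }
    )
    write_tsv(outdir / "entropy.tsv", entropy_table)
    record("entropy.tsv", outdir / "entropy.tsv")
    (outdir / "entropy_welch.json").write_text(json.dumps(entropy.to_dict(), indent=2) + "\n")
    record("entropy_welch.json", outdir / "entropy_welch.json")
    manifest["stages"]["entropy"] = entropy.to_dict()

    # -- core Ka/Ks -------------------------------------------------------
    kaks_families = core if config.kaks_max_families is None else core[: config.kaks_max_families]
    rows = []
    for family_id in kaks_families:
        members = assignment.families[family_id]
        if len(members) < 2:
            continue
        aln = codon_align([(g, cds_by_gene[g]) for g in members])
        rec = family_omega(aln)
        row = {"family_id": family_id, **rec.as_row(), "valid": rec.valid}
        rows.append(row)
    kaks_table = pd.DataFrame(rows)
    write_tsv(outdir / "core_kaks.tsv", kaks_table)
    record("core_kaks.tsv", outdir / "core_kaks.tsv")
    defined = kaks_table[kaks_table["omega_defined"] == True] if len(kaks_table) else kaks_table  # noqa: E712
    manifest["stages"]["kaks"] = {
        "n_families": len(kaks_table),
        "n_omega_defined": int(len(defined)),
        "mean_omega": float(defined["omega"].mean()) if len(defined) else float("nan"),
        "all_omega_below_1": bool((defined["omega"] < 1).all()) if len(defined) else False,
    }

    # -- feature correlations --------------------------------------------
    if config.feature_table:
        table = read_tsv(config.feature_table)
        report = correlate_with_genome_size(table, alpha=config.correlation_alpha)
        write_tsv(outdir / "correlations.tsv", report)
        record("correlations.tsv", outdir / "correlations.tsv")
        manifest["stages"]["correlations"] = {
            "n_features": len(report),
            "n_significant": int(report["significant"].sum()),
        }

    # -- interolog transfer ----------------------------------------------
    if config.microbe_hits and config.host_hits and config.template_edges:
        thresholds = HomologyFilter(
            evalue_max=config.interolog_evalue_max,
            identity_min=config.interolog_identity_min,
            query_cov_min=config.interolog_query_cov_min,
            template_cov_min=config.interolog_template_cov_min,
        )
        mh = _load_hits(config.microbe_hits)
        hh = _load_hits(config.host_hits)
        edges = predict_interologs(mh, hh, read_tsv(config.template_edges), thresholds)
        write_tsv(outdir / "predicted_ppi.tsv", edges)
        record("predicted_ppi.tsv", outdir / "predicted_ppi.tsv")
        manifest["stages"]["interolog"] = summarize_network(edges)

    config.to_yaml(outdir / "config.yaml")
    record("config.yaml", outdir / "config.yaml")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _load_hits(path: str) -> pd.DataFrame:
    """Native hit TSV (named columns) or 14-column BLAST tabular."""
    first = Path(path).open().readline()
    if "query_id" in first:
        table = read_tsv(path)
        if "template_id" not in table.columns and "subject_id" in table.columns:
            table = table.rename(columns={"subject_id": "template_id"})
        return table
    return read_blast_tab(path, coverage_columns=True)
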