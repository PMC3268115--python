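"""End-to-end orchestration: hits -> RBB -> matrix -> filter -> classify -> report.

A single declarative configuration (YAML-friendly dataclass) names the
inputs and every threshold; :func:`run_pipeline` executes the stages, writes
the stage outputs (matrix TSV, classification TSV, overlap JSON/TSV,
permutation JSON) and returns a run report.  Identical configuration and
seed give identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .errors import ConfigError, InputError
from .expression import fold_change_from_median, monte_carlo_enrichment
from .orthology import parse_hits, rbb_pairs
from .overlap import format_percentage, read_id_list, summarize_overlap
from .profiling import OrthologueMatrix, SpeciesPanel, build_matrix, filter_min_species, read_panel
from .scoring import classify_all

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "summarize_run"]


@dataclass
class PipelineConfig:
    """Paths and parameters for one pipeline run.

    Exactly one of ``hits_dir`` (forward/reverse hit tables named
    ``<ref>__<species>.tsv`` / ``<species>__<ref>.tsv``) or ``matrix_tsv``
    (a prebuilt presence matrix) must be supplied.  Thresholds default to
    the screen's published operating point.
    """

    panel_tsv: str | Path = ""
    hits_dir: str | Path | None = None
    matrix_tsv: str | Path | None = None
    reference_proteins: str | Path | None = None  # one-ID-per-line; required with hits_dir
    proteomic_reference: str | Path | None = None  # known ciliary-proteome IDs
    expression_tsv: str | Path | None = None
    pollen_stage: str = "mature_pollen"
    enrichment_gene_set: str | Path | None = None  # defaults to the CCP set
    evalue_threshold: float = 1e-5
    min_species: int = 5
    ciliary_threshold: int = 10
    ccp_beta: int = 18
    ccp_mu: int = 2
    n_sets: int = 22640
    seed: int = 0
    output_dir: str | Path = "pipeline_out"

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if not self.panel_tsv:
            raise ConfigError("config missing required input: panel")
        if (self.hits_dir is None) == (self.matrix_tsv is None):
            raise ConfigError("exactly one of hits_dir / matrix_tsv must be supplied")
        if self.hits_dir is not None and self.reference_proteins is None:
            raise ConfigError("hits_dir input requires reference_proteins")
        for name in ("panel_tsv", "hits_dir", "matrix_tsv", "reference_proteins",
                     "proteomic_reference", "expression_tsv", "enrichment_gene_set"):
            value = getattr(self, name)
            if value is not None and value != "" and not Path(value).exists():
                raise InputError(f"{name}: path not found: {value}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _matrix_from_hits(config: PipelineConfig, panel: SpeciesPanel) -> OrthologueMatrix:
    hits_dir = Path(config.hits_dir)
    ref = panel.query_species_id
    reference_proteins = sorted(read_id_list(config.reference_proteins))
    pairs = []
    for species in panel.species_ids:
        if species == ref:
            continue
        fwd_path = hits_dir / f"{ref}__{species}.tsv"
        rev_path = hits_dir / f"{species}__{ref}.tsv"
        if not fwd_path.exists() or not rev_path.exists():
            raise InputError(f"missing hit tables for species {species}: {fwd_path} / {rev_path}")
        with open(fwd_path) as fh:
            fwd = parse_hits(fh, source=ref, target=species)
        with open(rev_path) as fh:
            rev = parse_hits(fh, source=species, target=ref)
        pairs.extend(rbb_pairs(fwd, rev, reference_proteins, config.evalue_threshold))
        logger.info("RBB %s: %d hits fwd, %d rev", species, len(fwd), len(rev))
    return build_matrix(pairs, panel, reference_proteins)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every configured stage and return the run report (also written as JSON)."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    panel = read_panel(config.panel_tsv)
    if config.matrix_tsv is not None:
        matrix = OrthologueMatrix.from_tsv(config.matrix_tsv, panel.query_species_id)
        if list(matrix.species_ids) != panel.species_ids:
            raise InputError("matrix columns do not match the panel's species")
    else:
        matrix = _matrix_from_hits(config, panel)
    n_input = len(matrix.protein_ids)
    n_with_orthologue = int((matrix.target_presence_counts() >= 1).sum())

    filtered = filter_min_species(matrix, config.min_species)
    filtered.to_tsv(outdir / "matrix_filtered.tsv")

    classification = classify_all(
        filtered, panel,
        ciliary_threshold=config.ciliary_threshold,
        ccp_beta=config.ccp_beta,
        ccp_mu=config.ccp_mu,
    )
    classification.to_csv(outdir / "classification.tsv", sep="\t")

    sets = {
        "ciliary_profile": set(classification.index[classification["ciliary_profile"]]),
        "ccp": set(classification.index[classification["ccp"]]),
        "fungal_retained": set(classification.index[classification["fungal_retained"]]),
        "leca": set(classification.index[classification["leca"]]),
    }

    overlaps = {}
    if config.proteomic_reference is not None:
        reference = read_id_list(config.proteomic_reference)
        for name in ("ciliary_profile", "ccp"):
            overlaps[name] = summarize_overlap(sets[name], reference, len(classification)).as_dict()
        json.dump(overlaps, open(outdir / "overlap.json", "w"), indent=2)

    permutation = None
    if config.expression_tsv is not None:
        expr = pd.read_csv(config.expression_tsv, sep="\t", index_col=0)
        fc = fold_change_from_median(expr).fc
        if config.enrichment_gene_set is not None:
            gene_set = sorted(read_id_list(config.enrichment_gene_set))
        else:
            gene_set = sorted(g for g in sets["ccp"] if g in fc.index)
        if gene_set:
            permutation = monte_carlo_enrichment(
                fc, gene_set, config.pollen_stage, n_sets=config.n_sets, seed=config.seed
            ).as_dict()
            json.dump(permutation, open(outdir / "permutation.json", "w"), indent=2)

    report = summarize_run(classification, overlaps, permutation)
    report["parameters"] = {
        "evalue_threshold": config.evalue_threshold,
        "min_species": config.min_species,
        "ciliary_threshold": config.ciliary_threshold,
        "ccp_beta": config.ccp_beta,
        "ccp_mu": config.ccp_mu,
        "n_sets": config.n_sets,
        "seed": config.seed,
    }
    report["inputs"] = {
        "panel": str(config.panel_tsv),
        "panel_sha256": _sha256(Path(config.panel_tsv)),
        "n_proteins_input": n_input,
        "n_with_orthologue": n_with_orthologue,
    }
    report["version"] = __version__
    json.dump(report, open(outdir / "report.json", "w"), indent=2)
    return report


def summarize_run(
    classification: pd.DataFrame,
    overlaps: dict[str, dict] | None = None,
    permutation: dict | None = None,
) -> dict[str, Any]:
    """Results-style summary: set sizes, percentages, novel counts, enrichment.

    Percentages are always recomputed here from the counts in the same
    report, never cached from elsewhere.
    """
    n = len(classification)
    counts = {
        "dataset_size": n,
        "ciliary_profile": int(classification["ciliary_profile"].sum()) if n else 0,
        "ccp": int(classification["ccp"].sum()) if n else 0,
        "fungal_retained": int(classification["fungal_retained"].sum()) if n else 0,
        "leca": int(classification["leca"].sum()) if n else 0,
    }
    report: dict[str, Any] = {"counts": counts, "percentages": {}}
    if n > 0:
        for name in ("ciliary_profile", "ccp", "fungal_retained", "leca"):
            report["percentages"][name] = format_percentage(counts[name], n)
    if overlaps:
        report["overlap"] = overlaps
    if permutation:
        report["enrichment"] = permutation
    return report
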