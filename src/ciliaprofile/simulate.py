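"""Synthetic data with planted ground truth for every pipeline stage.

The generators emulate the statistical structure the screen assumes, not
real sequences: species panels with the published composition (29 ciliated
plus 16 non-ciliated genomes, including 3 non-ciliated land plants),
presence/absence matrices with planted protein classes, matching
similarity-hit tables whose reciprocal-best-hit analysis reconstructs the
matrix, and expression matrices with a planted pollen-enriched gene set.

Planted profile classes (templates before noise):

``ubiquitous``
    present in every species — the LECA-like background;
``ciliary_profile``
    present in all ciliated species, absent from all non-ciliated ones;
``ccp``
    present in all ciliated species and all non-ciliated plants;
``fungal_retained``
    present in all ciliated species and all non-ciliated fungi;
``random``
    each cell present independently with probability ``background_presence``.

Noise then flips truly-absent cells to present with probability ``fp_rate``
and truly-present cells to absent with probability ``fn_rate``; the query
species' column is never flipped (the reference proteome defines the rows).
All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .orthology import HitRecord, HitTable
from .profiling import SUPERGROUPS, OrthologueMatrix, SpeciesPanel, SpeciesRecord

__all__ = [
    "ProfileGenerationConfig",
    "generate_panel",
    "generate_profiles",
    "generate_hit_tables",
    "generate_expression",
]

CLASS_LABELS = ("ubiquitous", "ciliary_profile", "ccp", "fungal_retained", "random")


@dataclass
class ProfileGenerationConfig:
    """Panel composition, planted class mixture and noise rates.

    Defaults mirror the published panel: 45 genomes, 29 ciliated and 16
    non-ciliated, of which 3 are non-ciliated land plants and 5 non-ciliated
    fungi.  Class counts are the numbers of proteins planted per template.
    """

    n_ciliated: int = 29
    n_nonciliated: int = 16
    n_nonciliated_plants: int = 3
    n_nonciliated_fungi: int = 5
    class_counts: dict[str, int] = field(
        default_factory=lambda: {
            "ubiquitous": 20,
            "ciliary_profile": 20,
            "ccp": 10,
            "fungal_retained": 5,
            "random": 45,
        }
    )
    background_presence: float = 0.3
    fp_rate: float = 0.0
    fn_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_nonciliated_plants + self.n_nonciliated_fungi > self.n_nonciliated:
            raise ConfigError("plants + fungi exceed the non-ciliated species count")
        if min(self.n_ciliated, self.n_nonciliated) < 0:
            raise ConfigError("negative species counts")
        for rate in (self.fp_rate, self.fn_rate, self.background_presence):
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"rate {rate} outside [0, 1]")
        unknown = set(self.class_counts) - set(CLASS_LABELS)
        if unknown:
            raise ConfigError(f"unknown class labels: {sorted(unknown)}")
        if any(v < 0 for v in self.class_counts.values()):
            raise ConfigError("negative class counts")


def generate_panel(config: ProfileGenerationConfig) -> SpeciesPanel:
    """Build a deterministic annotated species panel from the configuration.

    The query species is the first ciliated one (an Archaeplastida alga,
    standing in for the reference proteome's organism).  Remaining ciliated
    species cycle through all six supergroups; non-ciliated species are the
    configured plants (Archaeplastida), fungi (Fungi), and a remainder
    spread over Holozoa/Chromalveolata/Amoebozoa/Excavata.
    """
    config.validate()
    species: list[SpeciesRecord] = []
    for i in range(config.n_ciliated):
        sg = "Archaeplastida" if i == 0 else SUPERGROUPS[i % len(SUPERGROUPS)]
        species.append(
            SpeciesRecord(
                species_id=f"cil{i:02d}",
                ciliated=True,
                supergroup=sg,
                fungus=(sg == "Fungi"),
            )
        )
    for i in range(config.n_nonciliated_plants):
        species.append(
            SpeciesRecord(
                species_id=f"plant{i:02d}",
                ciliated=False,
                supergroup="Archaeplastida",
                nonciliated_plant=True,
            )
        )
    for i in range(config.n_nonciliated_fungi):
        species.append(
            SpeciesRecord(
                species_id=f"fungus{i:02d}", ciliated=False, supergroup="Fungi", fungus=True
            )
        )
    n_other = config.n_nonciliated - config.n_nonciliated_plants - config.n_nonciliated_fungi
    other_groups = ("Holozoa", "Chromalveolata", "Amoebozoa", "Excavata")
    for i in range(n_other):
        species.append(
            SpeciesRecord(
                species_id=f"noncil{i:02d}",
                ciliated=False,
                supergroup=other_groups[i % len(other_groups)],
            )
        )
    return SpeciesPanel(species=species, query_species_id="cil00")


def _class_template(label: str, panel: SpeciesPanel, rng: np.random.Generator, p_bg: float) -> np.ndarray:
    ciliated = np.array([s.ciliated for s in panel.species])
    plant = np.array([s.nonciliated_plant for s in panel.species])
    fungus_nc = np.array([s.fungus and not s.ciliated for s in panel.species])
    if label == "ubiquitous":
        return np.ones(len(panel), dtype=bool)
    if label == "ciliary_profile":
        return ciliated.copy()
    if label == "ccp":
        return ciliated | plant
    if label == "fungal_retained":
        return ciliated | fungus_nc
    if label == "random":
        return rng.random(len(panel)) < p_bg
    raise ConfigError(f"unknown class label {label!r}")


def generate_profiles(config: ProfileGenerationConfig) -> tuple[OrthologueMatrix, pd.Series]:
    """Generate a planted presence/absence matrix and its truth table.

    Returns the orthologue matrix (rows named ``<class><index>``) and a
    Series mapping each protein to its true class label.
    """
    config.validate()
    panel = generate_panel(config)
    rng = np.random.default_rng(config.seed)
    rows, labels, names = [], [], []
    for label in CLASS_LABELS:
        for i in range(config.class_counts.get(label, 0)):
            rows.append(_class_template(label, panel, rng, config.background_presence))
            labels.append(label)
            names.append(f"{label}{i:04d}")
    pres = (
        np.vstack(rows) if rows else np.zeros((0, len(panel)), dtype=bool)
    )
    if pres.size:
        flips_fp = rng.random(pres.shape) < config.fp_rate
        flips_fn = rng.random(pres.shape) < config.fn_rate
        noisy = np.where(pres, ~flips_fn, flips_fp)
        qcol = panel.species_ids.index(panel.query_species_id)
        noisy[:, qcol] = True  # the reference proteome defines the rows
        pres = noisy
    presence = pd.DataFrame(
        pres, index=pd.Index(names, name="protein_id"), columns=panel.species_ids
    )
    truth = pd.Series(labels, index=presence.index, name="true_class")
    return OrthologueMatrix(presence=presence, query_species_id=panel.query_species_id), truth


def generate_hit_tables(
    matrix: OrthologueMatrix,
    seed: int = 0,
    decoy_fraction: float = 0.0,
    extra_hit_fraction: float = 0.2,
) -> dict[str, tuple[HitTable, HitTable]]:
    """Emit forward/reverse similarity-hit tables realising a presence matrix.

    For every present cell (protein p, target species s) the tables contain
    a mutual-top pair of hits with e-values well below 1e-5: the forward top
    hit of p is the synthetic target protein ``s|p`` and the reverse top hit
    of ``s|p`` is p.  A fraction of present cells additionally receives a
    weaker, non-top forward hit (harmless decoy); ``decoy_fraction`` of
    present cells instead get their reciprocity broken — the reverse best
    hit is redirected to a different reference protein, so reciprocal-best
    analysis drops that cell.  With ``decoy_fraction = 0`` the round trip
    parse -> RBB -> matrix reconstructs the input exactly.

    Returns a mapping target species -> (forward table, reverse table);
    the query species has no tables (no search against itself).
    """
    rng = np.random.default_rng(seed)
    ref = matrix.query_species_id
    proteins = matrix.protein_ids
    out: dict[str, tuple[HitTable, HitTable]] = {}

    def _hit(q: str, s: str, e: float, bits: float) -> HitRecord:
        return HitRecord(
            query_id=q,
            subject_id=s,
            percent_identity=float(np.round(50 + 40 * rng.random(), 1)),
            aln_length=200,
            mismatches=10,
            gap_opens=1,
            q_start=1,
            q_end=200,
            s_start=1,
            s_end=200,
            e_value=e,
            bit_score=bits,
        )

    for species in matrix.species_ids:
        if species == ref:
            continue
        fwd = HitTable(source=ref, target=species)
        rev = HitTable(source=species, target=ref)
        col = matrix.presence[species]
        present = [p for p in proteins if col[p]]
        for p in present:
            ortho = f"{species}|{p}"
            broken = rng.random() < decoy_fraction and len(proteins) > 1
            fwd.records.append(_hit(p, ortho, 1e-50, 300.0))
            if broken:
                # reverse best points at some other reference protein
                others = [q for q in proteins if q != p]
                decoy_target = others[int(rng.integers(len(others)))]
                rev.records.append(_hit(ortho, decoy_target, 1e-60, 320.0))
                rev.records.append(_hit(ortho, p, 1e-50, 300.0))
            else:
                rev.records.append(_hit(ortho, p, 1e-50, 300.0))
            if rng.random() < extra_hit_fraction:
                # weaker secondary hit; never outranks the true one
                fwd.records.append(_hit(p, f"{species}|decoy_{p}", 1e-10, 80.0))
        out[species] = (fwd, rev)
    return out


def generate_expression(
    n_genes: int,
    stage_labels: list[str] | None = None,
    enriched_set_size: int = 21,
    effect: float = 3.0,
    noise_sd: float = 0.25,
    seed: int = 0,
    pollen_stage: str = "mature_pollen",
) -> tuple[pd.DataFrame, pd.Series]:
    """Generate a genes x stages expression matrix with a planted pollen signal.

    Background values are log-normal (log-mean 0, log-sd ``noise_sd``) per
    cell; the first ``enriched_set_size`` genes have their pollen-stage
    value multiplied by ``effect``.  ``effect = 1`` yields a fully
    exchangeable null dataset.  Returns the matrix and a truth Series with
    labels ``enriched`` / ``background``.
    """
    if stage_labels is None:
        stage_labels = [f"stage{i:02d}" for i in range(9)] + [pollen_stage]
    if pollen_stage not in stage_labels:
        raise ConfigError(f"pollen stage {pollen_stage!r} not among stage labels")
    if not 0 <= enriched_set_size <= n_genes:
        raise ConfigError("enriched_set_size must be within [0, n_genes]")
    if effect <= 0:
        raise ConfigError("effect must be positive")
    rng = np.random.default_rng(seed)
    values = np.exp(rng.normal(0.0, noise_sd, size=(n_genes, len(stage_labels))))
    genes = [f"g{i:05d}" for i in range(n_genes)]
    expr = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=stage_labels)
    expr.iloc[:enriched_set_size, expr.columns.get_loc(pollen_stage)] *= effect
    truth = pd.Series(
        ["enriched"] * enriched_set_size + ["background"] * (n_genes - enriched_set_size),
        index=expr.index,
        name="true_class",
    )
    return expr, truth
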