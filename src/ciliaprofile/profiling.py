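"""Phylogenetic profiles: presence/absence of orthologues over a species panel.

A protein's phylogenetic profile is its presence/absence vector across an
annotated panel of genomes.  The panel marks each species as ciliated (it
produces a centriole/cilium/flagellum at some life-cycle stage) or not,
assigns it to one of six eukaryotic supergroups, and flags the non-ciliated
land plants and the fungi.  Profiles are summarised per protein into the
counts the scoring rules consume:

``beta``
    ciliated species possessing an orthologue (the query species counts
    toward beta when it is ciliated — a reference protein trivially exists
    in its own proteome);
``alpha``
    non-ciliated species possessing an orthologue;
``mu``
    non-ciliated species excluding the non-ciliated plants;
``plant_count`` / ``fungal_nc_count`` / ``nonfungal_nc_count``
    the plant and fungal decompositions of alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .orthology import OrthologuePair

SUPERGROUPS = (
    "Archaeplastida",
    "Excavata",
    "Chromalveolata",
    "Holozoa",
    "Fungi",
    "Amoebozoa",
)

__all__ = [
    "SUPERGROUPS",
    "SpeciesRecord",
    "SpeciesPanel",
    "OrthologueMatrix",
    "ProfileCounts",
    "build_matrix",
    "filter_min_species",
    "count_categories",
    "profile_counts_table",
    "leca_set",
    "read_panel",
    "write_panel",
]


@dataclass(frozen=True)
class SpeciesRecord:
    """One genome in the panel, with its ciliation and taxonomy flags."""

    species_id: str
    ciliated: bool
    supergroup: str
    nonciliated_plant: bool = False
    fungus: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        if self.supergroup not in SUPERGROUPS:
            raise InputError(
                f"unknown supergroup {self.supergroup!r} for {self.species_id}; "
                f"expected one of {SUPERGROUPS}"
            )
        if self.nonciliated_plant and (self.ciliated or self.supergroup != "Archaeplastida"):
            raise InputError(
                f"{self.species_id}: a non-ciliated plant must be non-ciliated Archaeplastida"
            )
        if self.fungus and self.supergroup != "Fungi":
            raise InputError(f"{self.species_id}: fungus flag requires supergroup Fungi")


@dataclass
class SpeciesPanel:
    """Ordered species panel with a designated query (reference-proteome) species."""

    species: list[SpeciesRecord]
    query_species_id: str

    def __post_init__(self) -> None:
        ids = [s.species_id for s in self.species]
        if len(set(ids)) != len(ids):
            raise InputError("duplicate species_id in panel")
        if self.query_species_id not in ids:
            raise InputError(f"query species {self.query_species_id!r} not in panel")

    def __len__(self) -> int:
        return len(self.species)

    @property
    def species_ids(self) -> list[str]:
        return [s.species_id for s in self.species]

    @property
    def n_ciliated(self) -> int:
        return sum(s.ciliated for s in self.species)

    @property
    def n_nonciliated(self) -> int:
        return len(self.species) - self.n_ciliated

    def flags_frame(self) -> pd.DataFrame:
        """Panel flags as a DataFrame indexed by species_id (panel order)."""
        return pd.DataFrame(
            {
                "ciliated": [s.ciliated for s in self.species],
                "supergroup": [s.supergroup for s in self.species],
                "nonciliated_plant": [s.nonciliated_plant for s in self.species],
                "fungus": [s.fungus for s in self.species],
            },
            index=pd.Index(self.species_ids, name="species_id"),
        )


@dataclass
class OrthologueMatrix:
    """Proteins x species boolean presence, with optional per-cell orthologue ids.

    ``presence`` rows are reference-proteome proteins, columns follow the
    panel's species order.  The query-species column is all-present by
    construction.  ``orthologue_ids`` (same shape, object dtype) holds the
    target-proteome identifier behind each present cell where known.
    """

    presence: pd.DataFrame
    query_species_id: str
    orthologue_ids: pd.DataFrame | None = None

    @property
    def protein_ids(self) -> list[str]:
        return list(self.presence.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.presence.columns)

    def target_presence_counts(self) -> pd.Series:
        """Per-protein count of present *target* species (query column excluded)."""
        cols = [c for c in self.presence.columns if c != self.query_species_id]
        return self.presence[cols].sum(axis=1)

    def to_tsv(self, stream: IO[str] | str | Path) -> None:
        """Serialise as TSV: cells are 0 (absent), or the orthologue id / 1 (present)."""
        cells = self.presence.astype(object).copy()
        cells[:] = np.where(self.presence.to_numpy(), "1", "0")
        if self.orthologue_ids is not None:
            ids = self.orthologue_ids.to_numpy(dtype=object)
            mask = self.presence.to_numpy() & pd.notna(ids)
            cells[:] = np.where(mask, ids, cells.to_numpy(dtype=object))
        cells.index.name = "protein_id"
        cells.to_csv(stream, sep="\t")

    @classmethod
    def from_tsv(cls, stream: IO[str] | str | Path, query_species_id: str) -> "OrthologueMatrix":
        raw = pd.read_csv(stream, sep="\t", index_col=0, dtype=str)
        raw.index = raw.index.astype(str)
        presence = raw != "0"
        ids = raw.where(presence & (raw != "1"))
        return cls(presence=presence, query_species_id=query_species_id, orthologue_ids=ids)


@dataclass(frozen=True)
class ProfileCounts:
    """Per-protein category counts over the panel flags."""

    beta: int
    alpha: int
    mu: int
    plant_count: int
    fungal_nc_count: int
    nonfungal_nc_count: int

    def __post_init__(self) -> None:
        if self.mu + self.plant_count != self.alpha:
            raise InputError("mu + plant_count must equal alpha")
        if self.fungal_nc_count + self.nonfungal_nc_count != self.alpha:
            raise InputError("fungal_nc_count + nonfungal_nc_count must equal alpha")


def build_matrix(
    pairs: Iterable[OrthologuePair],
    panel: SpeciesPanel,
    reference_proteins: Sequence[str],
) -> OrthologueMatrix:
    """Assemble the presence/absence matrix from RBB orthologue pairs.

    Cell (p, s) is present iff some pair (p, ., s) exists or s is the query
    species; row order follows ``reference_proteins``.  Duplicate pairs for
    one cell are idempotent.

    Raises
    ------
    InputError
        If a pair references a species outside the panel or a protein
        outside ``reference_proteins``.
    """
    species_ids = panel.species_ids
    presence = pd.DataFrame(
        False,
        index=pd.Index(reference_proteins, name="protein_id"),
        columns=species_ids,
    )
    ids = pd.DataFrame(None, index=presence.index, columns=species_ids, dtype=object)
    known_species = set(species_ids)
    known_proteins = set(reference_proteins)
    bad_species = set()
    for pair in pairs:
        if pair.target_species not in known_species:
            bad_species.add(pair.target_species)
            continue
        if pair.query_protein not in known_proteins:
            raise InputError(f"pair references unknown reference protein {pair.query_protein!r}")
        presence.loc[pair.query_protein, pair.target_species] = True
        ids.loc[pair.query_protein, pair.target_species] = pair.target_protein
    if bad_species:
        raise InputError(f"pairs reference species not in panel: {sorted(bad_species)}")
    presence[panel.query_species_id] = True
    return OrthologueMatrix(
        presence=presence, query_species_id=panel.query_species_id, orthologue_ids=ids
    )


def filter_min_species(matrix: OrthologueMatrix, min_species: int = 5) -> OrthologueMatrix:
    """Retain proteins with orthologues identified in >= ``min_species`` target genomes.

    The query species is excluded from the count: the filter concerns
    identifiable hits in *other* genomes, and every reference protein is
    trivially present in its own proteome.  Row order is preserved; the
    filter is idempotent and monotone in ``min_species``.
    """
    if min_species < 0:
        raise InputError("min_species must be >= 0")
    keep = matrix.target_presence_counts() >= min_species
    return OrthologueMatrix(
        presence=matrix.presence.loc[keep],
        query_species_id=matrix.query_species_id,
        orthologue_ids=None if matrix.orthologue_ids is None else matrix.orthologue_ids.loc[keep],
    )


def count_categories(row: Sequence[bool] | pd.Series, panel: SpeciesPanel) -> ProfileCounts:
    """Summarise one presence vector (panel order) into :class:`ProfileCounts`."""
    vec = np.asarray(row, dtype=bool)
    if vec.shape != (len(panel),):
        raise InputError(f"presence vector length {vec.size} != panel size {len(panel)}")
    ciliated = np.array([s.ciliated for s in panel.species])
    plant = np.array([s.nonciliated_plant for s in panel.species])
    fungus = np.array([s.fungus for s in panel.species])
    noncil = ~ciliated
    return ProfileCounts(
        beta=int((vec & ciliated).sum()),
        alpha=int((vec & noncil).sum()),
        mu=int((vec & noncil & ~plant).sum()),
        plant_count=int((vec & plant).sum()),
        fungal_nc_count=int((vec & noncil & fungus).sum()),
        nonfungal_nc_count=int((vec & noncil & ~fungus).sum()),
    )


def profile_counts_table(matrix: OrthologueMatrix, panel: SpeciesPanel) -> pd.DataFrame:
    """Vectorised :func:`count_categories` over every row of the matrix.

    Returns a DataFrame indexed by protein_id with columns beta, alpha, mu,
    plant_count, fungal_nc_count, nonfungal_nc_count.
    """
    if list(matrix.species_ids) != panel.species_ids:
        raise InputError("matrix columns do not match panel species order")
    pres = matrix.presence.to_numpy(dtype=bool)
    ciliated = np.array([s.ciliated for s in panel.species])
    plant = np.array([s.nonciliated_plant for s in panel.species])
    fungus = np.array([s.fungus for s in panel.species])
    noncil = ~ciliated
    return pd.DataFrame(
        {
            "beta": pres[:, ciliated].sum(axis=1),
            "alpha": pres[:, noncil].sum(axis=1),
            "mu": pres[:, noncil & ~plant].sum(axis=1),
            "plant_count": pres[:, plant].sum(axis=1),
            "fungal_nc_count": pres[:, noncil & fungus].sum(axis=1),
            "nonfungal_nc_count": pres[:, noncil & ~fungus].sum(axis=1),
        },
        index=matrix.presence.index,
    )


def leca_set(matrix: OrthologueMatrix, panel: SpeciesPanel) -> set[str]:
    """Proteins with an orthologue in every one of the six eukaryotic supergroups.

    Presence in all six groups is most parsimoniously explained by presence
    in the last eukaryotic common ancestor.  The query species counts toward
    its own supergroup.
    """
    pres = matrix.presence.to_numpy(dtype=bool)
    groups = np.array([s.supergroup for s in panel.species])
    in_all = np.ones(pres.shape[0], dtype=bool)
    for g in SUPERGROUPS:
        in_all &= pres[:, groups == g].any(axis=1)
    return set(matrix.presence.index[in_all])


_PANEL_COLUMNS = ["species_id", "name", "ciliated", "supergroup", "nonciliated_plant", "fungus"]


def write_panel(panel: SpeciesPanel, stream: IO[str] | str | Path) -> None:
    """Write the panel as TSV (query species marked by a header comment)."""
    df = pd.DataFrame(
        [
            {
                "species_id": s.species_id,
                "name": s.name or s.species_id,
                "ciliated": int(s.ciliated),
                "supergroup": s.supergroup,
                "nonciliated_plant": int(s.nonciliated_plant),
                "fungus": int(s.fungus),
            }
            for s in panel.species
        ],
        columns=_PANEL_COLUMNS,
    )
    if isinstance(stream, (str, Path)):
        with open(stream, "w") as fh:
            fh.write(f"# query_species: {panel.query_species_id}\n")
            df.to_csv(fh, sep="\t", index=False)
    else:
        stream.write(f"# query_species: {panel.query_species_id}\n")
        df.to_csv(stream, sep="\t", index=False)


def read_panel(path: str | Path, query_species_id: str | None = None) -> SpeciesPanel:
    """Read a panel TSV; the query species comes from the header comment unless given."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    header_query = None
    if first.startswith("# query_species:"):
        header_query = first.split(":", 1)[1].strip()
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    records = [
        SpeciesRecord(
            species_id=row["species_id"],
            ciliated=bool(int(row["ciliated"])),
            supergroup=row["supergroup"],
            nonciliated_plant=bool(int(row["nonciliated_plant"])),
            fungus=bool(int(row["fungus"])),
            name=row.get("name", "") or "",
        )
        for _, row in df.iterrows()
    ]
    query = query_species_id or header_query
    if query is None:
        raise InputError(f"panel file {path} does not name a query species")
    return SpeciesPanel(species=records, query_species_id=query)
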