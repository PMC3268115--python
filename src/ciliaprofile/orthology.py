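"""Reciprocal-best-hit (RBB) orthology inference from tabular similarity output.

Two proteins in two proteomes are called putative orthologues when each is
the other's top similarity hit below an e-value threshold.  The functions
here consume the de facto 12-column tabular layout (``qseqid sseqid pident
length mismatch gapopen qstart qend sstart send evalue bitscore``) produced
by BLAST-family tools with ``-outfmt 6``; running the search itself is out
of scope.

Conventions applied throughout (deterministic and order-independent):

* the e-value threshold is strict (``e < threshold``) and applied in both
  search directions;
* "top hit" means minimum e-value; ties are broken by highest bit score,
  then lexicographically smallest subject identifier;
* several lines for the same (query, subject) pair collapse to the one with
  the lowest e-value (then highest bit score);
* self-hits (``query_id == subject_id``) are ignored;
* an e-value of 0.0 beats any positive e-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

from .errors import ConfigError, HitParseError

__all__ = [
    "HitRecord",
    "HitTable",
    "OrthologuePair",
    "parse_hits",
    "best_hit",
    "reciprocal_best",
    "rbb_pairs",
    "write_pairs",
]


@dataclass(frozen=True)
class HitRecord:
    """One similarity hit: a single line of 12-column tabular output."""

    query_id: str
    subject_id: str
    percent_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if not self.query_id or not self.subject_id:
            raise ValueError("query_id and subject_id must be non-empty")
        if self.e_value < 0:
            raise ValueError(f"negative e-value: {self.e_value}")
        if self.bit_score < 0:
            raise ValueError(f"negative bit score: {self.bit_score}")


@dataclass
class HitTable:
    """All hits for one ordered proteome pair (source searched against target)."""

    source: str
    target: str
    records: list[HitRecord] = field(default_factory=list)

    def __iter__(self) -> Iterator[HitRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def by_query(self, query: str) -> list[HitRecord]:
        return [r for r in self.records if r.query_id == query]


@dataclass(frozen=True)
class OrthologuePair:
    """An inferred orthologue: at most one per (query protein, target species)."""

    query_protein: str
    target_protein: str
    target_species: str


def parse_hits(stream: IO[str] | Iterable[str], source: str, target: str) -> HitTable:
    """Parse 12-column tab-separated similarity output into a :class:`HitTable`.

    Lines beginning with ``#`` and blank lines are skipped.  Values are kept
    exactly as parsed and nothing is filtered here — thresholds apply later.
    An empty stream yields an empty table.

    Raises
    ------
    HitParseError
        If a line has fewer than 12 fields or a field fails to parse; the
        error names the offending (1-based) line number.
    """
    table = HitTable(source=source, target=target)
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise HitParseError(lineno, f"expected >= 12 tab-separated fields, got {len(fields)}")
        try:
            rec = HitRecord(
                query_id=fields[0],
                subject_id=fields[1],
                percent_identity=float(fields[2]),
                aln_length=int(fields[3]),
                mismatches=int(fields[4]),
                gap_opens=int(fields[5]),
                q_start=int(fields[6]),
                q_end=int(fields[7]),
                s_start=int(fields[8]),
                s_end=int(fields[9]),
                e_value=float(fields[10]),
                bit_score=float(fields[11]),
            )
        except ValueError as exc:
            raise HitParseError(lineno, str(exc)) from exc
        table.records.append(rec)
    return table


def _hit_rank_key(rec: HitRecord) -> tuple[float, float, str]:
    # Minimise e-value; break ties by highest bit score, then smallest subject id.
    return (rec.e_value, -rec.bit_score, rec.subject_id)


def best_hit(table: HitTable, query: str, evalue_threshold: float = 1e-5) -> HitRecord | None:
    """Return ``query``'s top hit with ``e_value < evalue_threshold``, or None.

    Self-hits are ignored, and multiple lines for the same subject collapse
    to the best one before selection.  Absence of a passing hit is a valid
    result, not an error.
    """
    candidates: dict[str, HitRecord] = {}
    for rec in table.records:
        if rec.query_id != query or rec.subject_id == query:
            continue
        if not rec.e_value < evalue_threshold:
            continue
        prev = candidates.get(rec.subject_id)
        if prev is None or _hit_rank_key(rec) < _hit_rank_key(prev):
            candidates[rec.subject_id] = rec
    if not candidates:
        return None
    return min(candidates.values(), key=_hit_rank_key)


def reciprocal_best(
    forward: HitTable,
    reverse: HitTable,
    query: str,
    evalue_threshold: float = 1e-5,
) -> OrthologuePair | None:
    """Infer the RBB orthologue of ``query`` in the target proteome, if any.

    ``forward`` holds reference-against-target hits and ``reverse`` the
    target-against-reference direction.  The same strict threshold is
    applied in both directions; a non-reciprocating top hit yields None.

    Raises
    ------
    ConfigError
        If the two tables are not a matched ordered pair.
    """
    if forward.source != reverse.target or forward.target != reverse.source:
        raise ConfigError(
            f"mismatched proteome pair: forward {forward.source}->{forward.target}, "
            f"reverse {reverse.source}->{reverse.target}"
        )
    f = best_hit(forward, query, evalue_threshold)
    if f is None:
        return None
    back = best_hit(reverse, f.subject_id, evalue_threshold)
    if back is None or back.subject_id != query:
        return None
    return OrthologuePair(
        query_protein=query,
        target_protein=f.subject_id,
        target_species=forward.target,
    )


def rbb_pairs(
    forward: HitTable,
    reverse: HitTable,
    queries: Iterable[str],
    evalue_threshold: float = 1e-5,
) -> list[OrthologuePair]:
    """Run :func:`reciprocal_best` over many queries; drops the misses."""
    out = []
    for q in queries:
        pair = reciprocal_best(forward, reverse, q, evalue_threshold)
        if pair is not None:
            out.append(pair)
    return out


def write_pairs(pairs: Iterable[OrthologuePair], stream: IO[str]) -> None:
    """Write orthologue pairs as 3-column TSV: query, target species, target protein."""
    for p in pairs:
        stream.write(f"{p.query_protein}\t{p.target_species}\t{p.target_protein}\n")
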