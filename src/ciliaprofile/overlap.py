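"""Cross-referencing classified sets against reference ciliary-proteome lists.

A candidate set (e.g. the ciliary-profile proteins) is split into the part
already detected in proteomic studies of cilia and the novel remainder.
Intersection is exact-string; mapping between identifier namespaces is the
caller's concern.

Percentages are rendered to 1 decimal place when >= 1%, otherwise 2 decimal
places, rounding half away from zero — the convention that reproduces every
summary figure this screen reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable

__all__ = [
    "OverlapSummary",
    "intersect_with_reference",
    "format_percentage",
    "summarize_overlap",
    "read_id_list",
]


def intersect_with_reference(
    candidate_set: Iterable[str],
    reference: Iterable[str],
) -> tuple[set[str], set[str]]:
    """Split candidates into (detected, novel) against a reference ID list.

    ``detected`` is the exact-string intersection, ``novel`` the remainder;
    the two partition the candidate set.
    """
    candidates = set(candidate_set)
    ref = set(reference)
    detected = candidates & ref
    return detected, candidates - detected


def format_percentage(numerator: int, denominator: int) -> str:
    """Render ``100 * numerator / denominator`` with a trailing ``%``.

    1 decimal place when the value is >= 1, else 2; half rounds away from
    zero.  A zero denominator is an arithmetic error.
    """
    if denominator == 0:
        raise ZeroDivisionError("format_percentage: denominator is zero")
    if not 0 <= numerator <= denominator:
        raise ValueError(f"numerator {numerator} outside [0, {denominator}]")
    value = 100.0 * numerator / denominator
    ndigits = 1 if value >= 1 else 2
    scale = 10**ndigits
    # round-half-away-from-zero (values here are non-negative)
    rounded = int(value * scale + 0.5) / scale
    return f"{rounded:.{ndigits}f}%"


@dataclass(frozen=True)
class OverlapSummary:
    """Counts and formatted percentages for one candidate set vs a reference."""

    dataset_size: int
    set_size: int
    detected_in_proteomics: int
    novel: int
    pct_of_dataset: str
    pct_detected: str

    def as_dict(self) -> dict:
        return {
            "dataset_size": self.dataset_size,
            "set_size": self.set_size,
            "detected_in_proteomics": self.detected_in_proteomics,
            "novel": self.novel,
            "pct_of_dataset": self.pct_of_dataset,
            "pct_detected": self.pct_detected,
        }


def summarize_overlap(
    candidate_set: Iterable[str],
    reference: Iterable[str],
    dataset_size: int,
) -> OverlapSummary:
    """Build the summary a results table prints for one classified set."""
    detected, novel = intersect_with_reference(candidate_set, reference)
    set_size = len(detected) + len(novel)
    return OverlapSummary(
        dataset_size=dataset_size,
        set_size=set_size,
        detected_in_proteomics=len(detected),
        novel=len(novel),
        pct_of_dataset=format_percentage(set_size, dataset_size) if dataset_size else "",
        pct_detected=format_percentage(len(detected), set_size) if set_size else "",
    )


def read_id_list(source: str | Path | IO[str]) -> set[str]:
    """Read a one-identifier-per-line text file; blank lines and # comments skipped."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            lines = fh.readlines()
    else:
        lines = list(source)
    return {ln.strip() for ln in lines if ln.strip() and not ln.lstrip().startswith("#")}
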