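"""Profile scoring and classification into ciliary-profile, CCP and fungal sets.

The score is the linear metric ``beta - 10 * alpha``: a hit in a ciliated
species counts +1, a hit in a non-ciliated species counts -10.  The heavy
negative weight tolerates false negatives (a few missing ciliated hits) far
better than false positives (spurious non-ciliated hits), which is what a
presence/absence screen over heterogeneous genome annotations needs.

Classification rules, all strict inequalities:

* ciliary profile:  score > 10;
* CCP ("conserved in ciliated and plants"):  beta > 18, mu < 2, and an
  orthologue in at least one non-ciliated plant;
* fungal-retained:  the exact mirror of CCP with the non-ciliated fungi in
  the plants' role (beta > 18, non-fungal non-ciliated count < 2, and a
  non-ciliated fungal orthologue).

All thresholds are keyword parameters so sensitivity analyses are possible;
the defaults are the screen's published operating point.
"""

from __future__ import annotations

import pandas as pd

from .profiling import OrthologueMatrix, ProfileCounts, SpeciesPanel, leca_set, profile_counts_table

__all__ = [
    "ciliary_score",
    "classify_ciliary",
    "classify_ccp",
    "classify_fungal_retained",
    "classify_all",
]


def ciliary_score(counts: ProfileCounts) -> int:
    """The profile metric ``beta - 10 * alpha``."""
    return counts.beta - 10 * counts.alpha


def classify_ciliary(score: int, threshold: int = 10) -> bool:
    """True iff the score is strictly above the threshold."""
    return score > threshold


def classify_ccp(
    counts: ProfileCounts,
    beta_min_exclusive: int = 18,
    mu_max_exclusive: int = 2,
) -> bool:
    """Conserved-in-ciliated-and-plants: beta > 18, mu < 2, and a plant orthologue.

    "With plant orthologues" is read as presence in at least one non-ciliated
    plant (the weaker reading), not in all of them.
    """
    return (
        counts.beta > beta_min_exclusive
        and counts.mu < mu_max_exclusive
        and counts.plant_count >= 1
    )


def classify_fungal_retained(
    counts: ProfileCounts,
    beta_min_exclusive: int = 18,
    nonfungal_max_exclusive: int = 2,
) -> bool:
    """Retained through fungal cilia loss: the CCP rule with fungi for plants."""
    return (
        counts.beta > beta_min_exclusive
        and counts.nonfungal_nc_count < nonfungal_max_exclusive
        and counts.fungal_nc_count >= 1
    )


def classify_all(
    matrix: OrthologueMatrix,
    panel: SpeciesPanel,
    ciliary_threshold: int = 10,
    ccp_beta: int = 18,
    ccp_mu: int = 2,
) -> pd.DataFrame:
    """Score and classify every protein in the matrix.

    Returns a DataFrame indexed by protein_id with the profile counts plus
    ``score``, ``ciliary_profile``, ``ccp``, ``fungal_retained`` and ``leca``
    columns — the classification table the pipeline writes out.
    """
    counts = profile_counts_table(matrix, panel)
    out = counts.copy()
    out["score"] = out["beta"] - 10 * out["alpha"]
    out["ciliary_profile"] = out["score"] > ciliary_threshold
    out["ccp"] = (out["beta"] > ccp_beta) & (out["mu"] < ccp_mu) & (out["plant_count"] >= 1)
    out["fungal_retained"] = (
        (out["beta"] > ccp_beta)
        & (out["nonfungal_nc_count"] < ccp_mu)
        & (out["fungal_nc_count"] >= 1)
    )
    leca = leca_set(matrix, panel)
    out["leca"] = out.index.isin(leca)
    return out
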