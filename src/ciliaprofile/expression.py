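"""Stage-wise expression analysis and the Monte Carlo set-enrichment test.

Expression values (genes x developmental stages, one stage designated the
mature-pollen stage) are first rescaled per gene to *fold change from
median*: each value divided by that gene's median across stages.  A gene
set's enrichment in a stage is the plain sum of its fold changes there, and
its significance is assessed against random same-size gene sets drawn from
the whole array.

The empirical p-value uses the (r + 1) / (N + 1) estimator by default,
where r is the number of random sets whose statistic is >= the observed one
(ties count as exceedances) and N the number of sets drawn; it can never be
exactly zero.  The plain r / N estimator is available via
``plus_one=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .errors import InputError

__all__ = [
    "FoldChangeResult",
    "PermutationResult",
    "fold_change_from_median",
    "set_sum_statistic",
    "monte_carlo_enrichment",
    "mean_fold_change",
    "heatmap_order",
]


@dataclass
class FoldChangeResult:
    """Fold-change matrix plus the genes excluded for a zero median."""

    fc: pd.DataFrame
    excluded: list[str]


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of the random-gene-set enrichment test."""

    observed_stat: float
    n_sets: int
    set_size: int
    n_exceed: int
    p_value: float
    seed: int
    mean_fc: float

    def as_dict(self) -> dict:
        return {
            "observed_stat": self.observed_stat,
            "n_sets": self.n_sets,
            "set_size": self.set_size,
            "n_exceed": self.n_exceed,
            "p_value": self.p_value,
            "seed": self.seed,
            "mean_fc": self.mean_fc,
        }


def _check_expression(expr: pd.DataFrame) -> None:
    if expr.shape[1] < 2:
        raise InputError("expression matrix needs >= 2 stages")
    if expr.columns.duplicated().any():
        raise InputError("stage labels must be unique")
    if (expr.to_numpy() < 0).any():
        raise InputError("expression values must be non-negative")


def fold_change_from_median(expr: pd.DataFrame, pseudocount: bool = False) -> FoldChangeResult:
    """Divide each gene's values by its median across stages.

    Genes whose median is zero have an undefined ratio; by default they are
    dropped and reported in ``excluded``.  With ``pseudocount=True`` the
    smallest positive value in the matrix is added to every cell first, so
    no gene is dropped.
    """
    _check_expression(expr)
    values = expr.astype(float)
    if pseudocount:
        positive = values.to_numpy()[values.to_numpy() > 0]
        if positive.size == 0:
            raise InputError("all-zero expression matrix")
        values = values + positive.min()
    medians = values.median(axis=1)
    zero = medians == 0
    fc = values.loc[~zero].div(medians.loc[~zero], axis=0)
    return FoldChangeResult(fc=fc, excluded=list(values.index[zero]))


def _pollen_values(fc: pd.DataFrame, gene_set, stage: str) -> np.ndarray:
    if stage not in fc.columns:
        raise InputError(f"unknown stage {stage!r}")
    genes = list(gene_set)
    missing = [g for g in genes if g not in fc.index]
    if missing:
        raise InputError(f"genes not in fold-change matrix: {missing[:5]}")
    return fc.loc[genes, stage].to_numpy(dtype=float)


def set_sum_statistic(fc: pd.DataFrame, gene_set, stage: str) -> float:
    """Sum of fold change over the gene set in one stage (0.0 for the empty set)."""
    return float(_pollen_values(fc, gene_set, stage).sum())


def mean_fold_change(fc: pd.DataFrame, gene_set, stage: str) -> float:
    """Arithmetic mean fold change of the set in one stage."""
    vals = _pollen_values(fc, gene_set, stage)
    if vals.size == 0:
        raise InputError("mean_fold_change: empty gene set")
    return float(vals.mean())


def monte_carlo_enrichment(
    fc: pd.DataFrame,
    gene_set,
    stage: str,
    n_sets: int = 22640,
    seed: int = 0,
    plus_one: bool = True,
    exclude_test_genes: bool = False,
) -> PermutationResult:
    """Test a gene set for enrichment in one stage against random same-size sets.

    Draws ``n_sets`` gene sets of the same size, each uniformly without
    replacement from all rows of ``fc`` (optionally excluding the test
    genes), computes the sum-of-fold-change statistic for each, and counts
    how many reach the observed value.  Fully determined by ``seed``.
    """
    genes = list(gene_set)
    if len(genes) == 0:
        raise InputError("gene set is empty")
    observed = set_sum_statistic(fc, genes, stage)
    mean_fc = mean_fold_change(fc, genes, stage)

    k = len(genes)
    if k >= len(fc.index):
        raise InputError(f"set size {k} must be smaller than the universe ({len(fc.index)} genes)")
    universe = fc.index if not exclude_test_genes else fc.index.difference(genes, sort=False)
    pool = fc.loc[universe, stage].to_numpy(dtype=float)
    if k > pool.size:
        raise InputError(f"set size {k} exceeds sampling pool of {pool.size} genes")

    rng = np.random.default_rng(seed)
    n_exceed = 0
    # chunked uniform-key selection: the k smallest of n iid uniforms index a
    # uniform k-subset; keeps memory bounded at ~32 MB per chunk
    chunk = max(1, min(n_sets, 4_000_000 // max(pool.size, 1)))
    done = 0
    while done < n_sets:
        m = min(chunk, n_sets - done)
        keys = rng.random((m, pool.size))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        stats = pool[idx].sum(axis=1)
        n_exceed += int((stats >= observed).sum())
        done += m
    if plus_one:
        p = (n_exceed + 1) / (n_sets + 1)
    else:
        p = n_exceed / n_sets
    return PermutationResult(
        observed_stat=observed,
        n_sets=n_sets,
        set_size=k,
        n_exceed=n_exceed,
        p_value=p,
        seed=seed,
        mean_fc=mean_fc,
    )


def heatmap_order(fc: pd.DataFrame, gene_set) -> list[str]:
    """Deterministic row order for heatmap display of a gene set.

    Average-linkage hierarchical clustering on Euclidean distances between
    log2 fold-change rows; ties and leaf order resolve by input order.
    Purely cosmetic — no statistic depends on it.  Zero fold changes are
    clipped to a small floor before the log so distances stay finite.
    """
    genes = list(gene_set)
    missing = [g for g in genes if g not in fc.index]
    if missing:
        raise InputError(f"genes not in fold-change matrix: {missing[:5]}")
    if len(genes) <= 1:
        return genes
    mat = np.log2(np.maximum(fc.loc[genes].to_numpy(dtype=float), 1e-12))
    z = linkage(mat, method="average", metric="euclidean")
    return [genes[i] for i in leaves_list(z)]
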