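"""Permutation nulls, empirical enrichment probabilities and overlap tests.

Empirical p-values throughout use the add-one (permutation-inclusive)
estimator ``(1 + #{null >= observed}) / (1 + n_iter)``: the observed
configuration counts as one permutation, so p is never exactly zero and a
run of 10^4 draws bottoms out at ~1e-4.

The mRNA-mRNA null is built from all cross-pair Spearman correlations
between two disjoint random gene sets (1000 x 1000 = one million pairs by
default); its 95th and 5th percentiles serve as correlation/anti-correlation
cutoffs for the driver correlation-count tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class NullDistribution:
    values: np.ndarray
    p95: float
    p05: float
    n_draws: int
    seed: int


def _rank_unit(matrix: np.ndarray) -> np.ndarray:
    """Row-wise ranks, centred and scaled to unit norm.

    The dot product of two such rows is the tie-corrected Spearman
    correlation of the original rows.  Constant rows become NaN.
    """
    ranks = stats.rankdata(matrix, axis=1)
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(ranks, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = ranks / norm
    unit[np.squeeze(norm, axis=1) == 0] = np.nan
    return unit


def spearman_cross(a: pd.DataFrame, b: pd.DataFrame) -> np.ndarray:
    """All pairwise Spearman correlations between rows of ``a`` and rows of ``b``."""
    if not a.columns.equals(b.columns):
        b = b[a.columns]
    return _rank_unit(a.to_numpy(float)) @ _rank_unit(b.to_numpy(float)).T


def mrna_mrna_null(expr: pd.DataFrame, n_pairs: int = 1_000_000, seed: int = 0) -> NullDistribution:
    """Null distribution of mRNA-mRNA Spearman correlations.

    Two disjoint gene sets of size ``sqrt(n_pairs)`` are drawn and all
    cross-pair correlations collected; the 95th/5th percentiles are the
    correlation cutoffs used downstream.
    """
    set_size = int(round(np.sqrt(n_pairs)))
    if expr.shape[0] < 2 * set_size:
        raise ValueError(
            f"need >= {2 * set_size} genes for two disjoint sets of {set_size};"
            f" have {expr.shape[0]} (use a smaller n_pairs)"
        )
    rng = np.random.default_rng(seed)
    picked = rng.choice(expr.shape[0], size=2 * set_size, replace=False)
    a = expr.iloc[picked[:set_size]]
    b = expr.iloc[picked[set_size:]]
    values = spearman_cross(a, b).ravel()
    values = values[~np.isnan(values)]
    return NullDistribution(
        values=values,
        p95=float(np.percentile(values, 95)),
        p05=float(np.percentile(values, 5)),
        n_draws=int(values.size),
        seed=seed,
    )


def geneset_size_matched_null(
    universe: Iterable[str],
    excluded: Iterable[str],
    set_size: int,
    statistic: Callable[[list[str]], float],
    observed: float,
    n_iter: int = 10_000,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Empirical enrichment p against size-matched random gene sets.

    Draws ``n_iter`` sets of ``set_size`` genes from ``universe`` minus
    ``excluded`` (e.g. the non-metabolic transcriptome), applies
    ``statistic`` to each, and returns the add-one upper-tail probability of
    the observed value plus the null draws.
    """
    pool = sorted(set(universe) - set(excluded))
    if len(pool) < set_size:
        raise ValueError(f"pool of {len(pool)} genes smaller than set size {set_size}")
    rng = np.random.default_rng(seed)
    pool_arr = np.array(pool)
    null = np.empty(n_iter)
    for i in range(n_iter):
        draw = pool_arr[rng.choice(len(pool_arr), size=set_size, replace=False)]
        null[i] = statistic(list(draw))
    p = (1 + int((null >= observed).sum())) / (1 + n_iter)
    return p, null


def correlation_count_table(
    metabolic: Sequence[str],
    drivers: Sequence[str],
    expr: pd.DataFrame,
    null: NullDistribution,
) -> pd.DataFrame:
    """Per-metabolic-gene counts of drivers beyond the null correlation cutoffs.

    ``correlated_count`` counts driver genes with rho above the null's 95th
    percentile, ``anticorrelated_count`` those below the 5th; self-pairs
    (a gene appearing in both lists) are excluded.
    """
    metabolic = [g for g in metabolic if g in expr.index]
    drivers = [g for g in drivers if g in expr.index]
    corr = spearman_cross(expr.loc[metabolic], expr.loc[drivers])
    for i, g in enumerate(metabolic):
        if g in drivers:
            corr[i, drivers.index(g)] = np.nan
    with np.errstate(invalid="ignore"):
        table = pd.DataFrame(
            {
                "correlated_count": (corr > null.p95).sum(axis=1),
                "anticorrelated_count": (corr < null.p05).sum(axis=1),
            },
            index=pd.Index(metabolic, name="gene_id"),
        )
    return table


def count_table_enrichment_p(
    table: pd.DataFrame,
    expr: pd.DataFrame,
    drivers: Sequence[str],
    null: NullDistribution,
    universe: Iterable[str] | None = None,
    n_iter: int = 10_000,
    seed: int = 0,
) -> pd.Series:
    """Empirical probability of each observed correlated-count by chance.

    One shared set of ``n_iter`` random genes (drawn from ``universe``,
    default: all expressed genes outside the driver list) is scored once;
    each cell's p is the add-one fraction of random genes whose
    correlated-count reaches the observed one.
    """
    if universe is None:
        universe = [g for g in expr.index if g not in set(drivers)]
    pool = sorted(set(universe))
    rng = np.random.default_rng(seed)
    draw = rng.choice(len(pool), size=n_iter, replace=len(pool) < n_iter)
    drawn_genes = [pool[i] for i in draw]
    unique = sorted(set(drawn_genes))
    null_counts = correlation_count_table(unique, list(drivers), expr, null)["correlated_count"]
    draws = null_counts.loc[drawn_genes].to_numpy()
    p = {
        gene: (1 + int((draws >= obs).sum())) / (1 + n_iter)
        for gene, obs in table["correlated_count"].items()
    }
    out = pd.Series(p, name="cell_p")
    out.index.name = "gene_id"
    return out


def hypergeometric_overlap(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> tuple[int, float, float]:
    """Exact hypergeometric overlap tails between two gene sets.

    Returns ``(overlap, p_enriched, p_depleted)`` where ``p_enriched`` is
    ``P(X >= overlap)`` and ``p_depleted`` is ``P(X <= overlap)`` for the
    hypergeometric draw of ``|b|`` genes from the universe containing
    ``|a|`` marked genes.
    """
    universe = set(universe)
    a = set(set_a)
    b = set(set_b)
    if not a <= universe or not b <= universe:
        raise ValueError("both sets must be subsets of the universe")
    k = len(a & b)
    M, n, N = len(universe), len(a), len(b)
    p_enriched = float(stats.hypergeom.sf(k - 1, M, n, N))
    p_depleted = float(stats.hypergeom.cdf(k, M, n, N))
    return k, p_enriched, p_depleted


def permutation_overlap_null(
    reference: Iterable[str],
    excluded_pool: Iterable[str],
    universe: Iterable[str],
    set_size: int,
    observed_overlap: int,
    side: str = "low",
    n_iter: int = 100_000,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Empirical overlap tail from random size-matched gene subsets.

    Draws ``n_iter`` subsets of ``set_size`` genes from ``universe`` minus
    ``excluded_pool`` and counts their overlap with ``reference``.  The
    requested tail ("low": P(overlap <= observed), "high": >=) is returned
    with the add-one estimator, together with the null overlap counts.
    Converges to the exact hypergeometric tail.
    """
    if side not in ("low", "high"):
        raise ValueError("side must be 'low' or 'high'")
    pool = sorted(set(universe) - set(excluded_pool))
    if len(pool) < set_size:
        raise ValueError(f"pool of {len(pool)} genes smaller than set size {set_size}")
    member = np.array([g in set(reference) for g in pool])
    rng = np.random.default_rng(seed)
    overlaps = np.empty(n_iter, dtype=int)
    chunk = max(1, min(n_iter, int(1e7 // max(len(pool), 1))))
    done = 0
    while done < n_iter:
        m = min(chunk, n_iter - done)
        keys = rng.random((m, len(pool)))
        idx = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
        overlaps[done : done + m] = member[idx].sum(axis=1)
        done += m
    if side == "low":
        hits = int((overlaps <= observed_overlap).sum())
    else:
        hits = int((overlaps >= observed_overlap).sum())
    return (1 + hits) / (1 + n_iter), overlaps


def frequently_mutated_genes(
    mutations: pd.DataFrame, n_samples: int, min_frequency: float = 0.05
) -> list[str]:
    """Genes somatically mutated in more than ``min_frequency`` of the cohort.

    Used to gate cancer-specific driver lists before correlation analysis.
    """
    per_gene = mutations.drop_duplicates(["gene_id", "sample_id"]).groupby("gene_id").size()
    freq = per_gene / float(n_samples)
    return sorted(freq.index[freq > min_frequency])
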