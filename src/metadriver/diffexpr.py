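"""Differential expression: Welch's t-test, BH adjustment, and selection rules.

Tumour-vs-normal comparisons use the unequal-variance t statistic with
Welch-Satterthwaite degrees of freedom on log2-scale abundance; the fold
change is the difference of group means on that scale.  Multiple testing is
controlled with the Benjamini-Hochberg step-up procedure.

Over-expression selection follows two stacked rules: a fold-change/q filter
(log2 fc > 0.5 and q < 0.05; the q condition can be dropped for cohorts
whose normal-tissue panel is too small for a stable q), then a top-decile
rank cut within the metabolic gene universe.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats


def welch_t(group_a, group_b) -> tuple[float, float, float]:
    """Welch's two-sided t-test plus the mean difference (log2 fold change).

    Returns ``(t_stat, p, log2_fc)`` with ``log2_fc = mean(a) - mean(b)``.
    Two groups with zero variance and equal means give ``t = 0, p = 1``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    fc = float(a.mean() - b.mean())
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if fc == 0:
            return 0.0, 1.0, 0.0
        return math.copysign(math.inf, fc), 0.0, fc
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue), fc


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped at 1.

    ``q_(i) = min_{j >= i} p_(j) * n / j`` over the sorted p-values, returned
    in the input order.
    """
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def differential_expression(tumour: pd.DataFrame, normal: pd.DataFrame) -> pd.DataFrame:
    """Per-gene Welch t-test of tumour vs normal expression with BH q-values.

    Matrices must share the gene index (harmonise the cohort first); all
    genes are tested and adjusted together.
    """
    genes = tumour.index
    if not genes.equals(normal.index):
        normal = normal.loc[genes]
    a = tumour.to_numpy(dtype=float)
    b = normal.to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")
    res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    fc = a.mean(axis=1) - b.mean(axis=1)
    degenerate = np.isnan(t)
    t[degenerate & (fc == 0)] = 0.0
    p[degenerate & (fc == 0)] = 1.0
    t[degenerate & (fc != 0)] = np.sign(fc[degenerate & (fc != 0)]) * np.inf
    p[degenerate & (fc != 0)] = 0.0
    return pd.DataFrame(
        {"log2_fc": fc, "t_stat": t, "p": p, "q": bh_adjust(p)},
        index=genes.rename("gene_id"),
    )


def select_overexpressed(
    de: pd.DataFrame, fc_min: float = 0.5, q_max: float = 0.05, use_q: bool = True
) -> set[str]:
    """Genes with log2 fc strictly above ``fc_min`` (and q strictly below
    ``q_max`` when ``use_q``)."""
    mask = de["log2_fc"] > fc_min
    if use_q:
        mask &= de["q"] < q_max
    return set(de.index[mask])


def select_underexpressed(
    de: pd.DataFrame, fc_min: float = 0.5, q_max: float = 0.05, use_q: bool = True
) -> set[str]:
    """Mirror of :func:`select_overexpressed` for the loss-side analysis."""
    mask = de["log2_fc"] < -fc_min
    if use_q:
        mask &= de["q"] < q_max
    return set(de.index[mask])


def top_decile_overexpressed(
    de: pd.DataFrame,
    metabolic: Iterable[str],
    use_q: bool = True,
    fc_min: float = 0.5,
    q_max: float = 0.05,
    fraction: float = 0.10,
    denominator: str = "all",
) -> set[str]:
    """Top over-expressed decile of the metabolic gene universe.

    Among metabolic genes passing :func:`select_overexpressed`, genes are
    ranked by descending log2 fold change and the top
    ``ceil(fraction * denominator size)`` kept; ties at the cut break to the
    smaller q, then lexicographically by gene id.  ``denominator`` is
    ``"all"`` (the full metabolic universe, default) or ``"passing"`` (only
    genes surviving the fold-change/q filter).
    """
    metabolic = [g for g in metabolic if g in de.index]
    sub = de.loc[metabolic]
    passers = sub.loc[sorted(select_overexpressed(sub, fc_min, q_max, use_q))]
    if denominator == "all":
        k = math.ceil(fraction * len(metabolic))
    elif denominator == "passing":
        k = math.ceil(fraction * len(passers))
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    ranked = passers.assign(_gene=passers.index).sort_values(
        ["log2_fc", "q", "_gene"], ascending=[False, True, True]
    )
    return set(ranked.index[: min(k, len(ranked))])


def mutation_stratified_de(
    expr: pd.DataFrame,
    mutations: pd.DataFrame,
    driver: str,
    targets: Iterable[str],
    fc_min: float = 1.0,
    q_max: float = 0.1,
) -> pd.DataFrame:
    """Mutant-vs-wild-type expression comparison stratified on one driver.

    Welch t-test per target gene between carriers and non-carriers of a
    somatic mutation in ``driver``; BH across the targets; significance flag
    ``|log2 fc| > fc_min and q < q_max``.
    """
    carriers = set(mutations.loc[mutations["gene_id"] == driver, "sample_id"])
    mut_samples = [s for s in expr.columns if s in carriers]
    wt_samples = [s for s in expr.columns if s not in carriers]
    if len(mut_samples) < 2 or len(wt_samples) < 2:
        raise ValueError(
            f"driver {driver!r} has {len(mut_samples)} mutant and"
            f" {len(wt_samples)} wild-type samples; need >= 2 of each"
        )
    targets = [g for g in targets if g in expr.index]
    rows = []
    for gene in targets:
        t, p, fc = welch_t(expr.loc[gene, mut_samples], expr.loc[gene, wt_samples])
        rows.append((gene, fc, t, p))
    de = pd.DataFrame(rows, columns=["gene_id", "log2_fc", "t_stat", "p"]).set_index("gene_id")
    de["q"] = bh_adjust(de["p"].to_numpy())
    de["significant"] = (de["log2_fc"].abs() > fc_min) & (de["q"] < q_max)
    return de
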