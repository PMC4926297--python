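"""Per-sample hypoxia scoring and hypoxia-association tests.

The hypoxia score summarises the expression of a validated hypoxia-response
gene signature in each tumour sample.  The default summary is the mean of
the within-cohort z-scored expression of the signature genes (zero-variance
genes are skipped); a median-of-ranks alternative is available.  Both are
monotone-equivalent to the common signature summary scores and invariant to
gene-wise affine rescaling.

Association tests mirror the downstream questions: do candidate driver genes
correlate with the hypoxia score more strongly than the remaining metabolic
genes (one-sided rank-sum test on the two sets of per-gene correlations),
and do samples with high hypoxia carry more copy-number gains of those genes
(Spearman plus a one-sided rank-sum on the median split)?
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .driver_pipeline import spearman


def hypoxia_score(expr: pd.DataFrame, signature: Iterable[str], method: str = "mean_z") -> pd.Series:
    """Per-sample summary of signature-gene expression.

    ``mean_z``: mean over signature genes of within-cohort z-scored
    expression; ``median_rank``: median over signature genes of the sample's
    rank (scaled to [0, 1]) in that gene's expression.
    """
    genes = [g for g in signature if g in expr.index]
    if not genes:
        raise ValueError("no signature genes present in the expression matrix")
    sub = expr.loc[genes]
    sd = sub.std(axis=1, ddof=1)
    sub = sub.loc[sd > 0]
    if sub.empty:
        raise ValueError("all signature genes have zero variance")
    if method == "mean_z":
        z = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=1), axis=0)
        score = z.mean(axis=0)
    elif method == "median_rank":
        ranks = sub.rank(axis=1) / sub.shape[1]
        score = ranks.median(axis=0)
    else:
        raise ValueError(f"unknown scoring method {method!r}")
    score.name = "hypoxia_score"
    return score


def gene_hypoxia_correlations(
    matrix: pd.DataFrame,
    scores: pd.Series,
    genes: Iterable[str],
    exclude: Iterable[str] = (),
) -> pd.Series:
    """Spearman correlation of each gene's profile with the hypoxia score.

    ``matrix`` may be expression or copy-number log2 ratios.  Genes in
    ``exclude`` (typically the hypoxia signature itself, to avoid
    self-correlation) are always removed from the test set first.
    """
    exclude = set(exclude)
    test = [g for g in genes if g in matrix.index and g not in exclude]
    if not test:
        raise ValueError("no genes left to test after exclusion")
    samples = scores.index.intersection(matrix.columns)
    rhos = {}
    for gene in test:
        rho, _ = spearman(matrix.loc[gene, samples], scores.loc[samples])
        rhos[gene] = rho
    out = pd.Series(rhos, name="rho")
    out.index.name = "gene_id"
    return out


def signature_vs_other_test(sig_rhos, other_rhos) -> float:
    """One-sided rank-sum p that the signature correlations are stochastically greater.

    Exact distribution when both groups have n <= 50 and there are no ties;
    normal approximation with continuity correction otherwise.
    """
    a = np.asarray(sig_rhos, dtype=float)
    b = np.asarray(other_rhos, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both correlation vectors must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size <= 50 and b.size <= 50 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="greater", method=method, use_continuity=True)
    return float(res.pvalue)


def hypoxia_scna_association(scores: pd.Series, per_sample_gained: pd.Series) -> tuple[float, float]:
    """Association between hypoxia and the per-sample gained fraction of a gene set.

    Returns the Spearman rho between the hypoxia score and the gained
    fraction, and a one-sided rank-sum p comparing gained fractions of
    upper-median vs lower-median hypoxia samples.  Constant gained fractions
    give ``(nan, 1.0)``.
    """
    samples = scores.index.intersection(per_sample_gained.index)
    s = scores.loc[samples].to_numpy(dtype=float)
    g = per_sample_gained.loc[samples].to_numpy(dtype=float)
    ok = ~(np.isnan(s) | np.isnan(g))
    s, g = s[ok], g[ok]
    if np.all(g == g[0]):
        return float("nan"), 1.0
    rho, _ = spearman(s, g)
    high = g[s > np.median(s)]
    low = g[s <= np.median(s)]
    res = stats.mannwhitneyu(high, low, alternative="greater", method="asymptotic", use_continuity=True)
    return rho, float(res.pvalue)
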