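"""The candidate-driver cascade.

A gene is a candidate driver within a cohort when it is (1) over-expressed
in tumours relative to normal tissue, (2) recurrently gained or amplified in
at least 20 % of samples, and (3) its expression correlates with its copy
number dosage (Spearman rho > 0.3 at BH q < 1e-3, adjusted over the genes
tested within the cohort).  Candidates recurring in at least three cohorts
form the cross-cancer core signature.  A mirrored loss-side cascade screens
under-expressed, recurrently lost genes for dosage-concordant silencing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust, differential_expression, top_decile_overexpressed, select_underexpressed
from .io_core import CohortBundle
from .scna import altered_fractions, call_scna

CANDIDATE_COLUMNS = ["gene_id", "cohort", "log2_fc", "gain_fraction", "rho", "rho_q", "passes"]


@dataclass
class CoreSignature:
    """Genes passing the per-cohort cascade in at least ``min_cancers`` cohorts."""

    genes: set[str]
    inclusion_count: pd.Series  # all genes passing in >= 1 cohort
    min_cancers: int


def spearman(x, y) -> tuple[float, float]:
    """Tie-corrected Spearman correlation with pairwise deletion of missing pairs.

    Returns ``(rho, p)``; a constant vector makes rho undefined and returns
    ``(nan, nan)`` rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 4:
        raise ValueError("need at least 4 paired non-missing values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def _screen(
    cohort: CohortBundle,
    selected: Iterable[str],
    fraction_col: str,
    frac_min: float,
    rho_min: float,
    q_max: float,
    de: pd.DataFrame | None,
) -> pd.DataFrame:
    if cohort.scna_calls is None:
        calls = call_scna(cohort.cn_log2)
    else:
        calls = cohort.scna_calls
    fractions = altered_fractions(calls)[fraction_col]
    selected = [g for g in selected if g in cohort.tumour_expr.index]
    tested = [g for g in selected if fractions.get(g, 0) >= frac_min]
    rows = []
    for gene in tested:
        rho, p = spearman(cohort.tumour_expr.loc[gene], cohort.cn_log2.loc[gene])
        fc = float(de.loc[gene, "log2_fc"]) if de is not None and gene in de.index else np.nan
        rows.append((gene, cohort.name, fc, float(fractions[gene]), rho, p))
    table = pd.DataFrame(rows, columns=["gene_id", "cohort", "log2_fc", "gain_fraction", "rho", "p"])
    q = np.full(len(table), np.nan)
    defined = table["p"].notna().to_numpy()
    if defined.any():
        q[defined] = bh_adjust(table.loc[defined, "p"].to_numpy())
    table["rho_q"] = q
    table["passes"] = (
        (table["gain_fraction"] >= frac_min)
        & (table["rho"] > rho_min)
        & (table["rho_q"] < q_max)
    ).fillna(False)
    return table[CANDIDATE_COLUMNS]


def candidate_drivers(
    cohort: CohortBundle,
    overexpressed: Iterable[str],
    gain_min: float = 0.2,
    rho_min: float = 0.3,
    q_max: float = 1e-3,
    de: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-cohort driver candidates among over-expressed, recurrently gained genes.

    The gain filter uses >= ("at least 20 %"); the correlation and q filters
    are strict.  The BH adjustment universe is the genes actually tested in
    this cohort (post gain-filter).
    """
    return _screen(cohort, overexpressed, "gained_fraction", gain_min, rho_min, q_max, de)


def loss_side_candidates(
    cohort: CohortBundle,
    underexpressed: Iterable[str],
    loss_min: float = 0.2,
    rho_min: float = 0.3,
    q_max: float = 1e-3,
    de: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Mirror cascade: under-expressed, recurrently lost, dosage-concordant genes.

    Correlation is still required to be positive (low dosage with low
    expression), so the same rho threshold applies.
    """
    return _screen(cohort, underexpressed, "loss_fraction", loss_min, rho_min, q_max, de)


def core_signature(
    candidates: Mapping[str, pd.DataFrame] | Iterable[pd.DataFrame],
    min_cancers: int = 3,
) -> CoreSignature:
    """Assemble the cross-cancer core signature from per-cohort candidate tables."""
    if isinstance(candidates, Mapping):
        tables = list(candidates.values())
    else:
        tables = list(candidates)
    passers = [t.loc[t["passes"], "gene_id"] for t in tables]
    if passers:
        counts = pd.concat(passers).value_counts().sort_index()
    else:
        counts = pd.Series(dtype=int)
    counts.index.name = "gene_id"
    genes = set(counts.index[counts >= min_cancers])
    return CoreSignature(genes=genes, inclusion_count=counts, min_cancers=min_cancers)


def run_driver_cascade(
    cohorts: Iterable[CohortBundle],
    metabolic: Iterable[str] | None = None,
    fc_min: float = 0.5,
    q_max_de: float = 0.05,
    use_q: bool = True,
    top_fraction: float = 0.10,
    gain_min: float = 0.2,
    rho_min: float = 0.3,
    q_max_rho: float = 1e-3,
    min_cancers: int = 3,
) -> tuple[dict[str, pd.DataFrame], CoreSignature]:
    """Full gain-side cascade over several cohorts.

    Per cohort: tumour-vs-normal differential expression, top-decile
    over-expression selection within the metabolic universe, gain filter,
    dosage correlation; then cross-cohort assembly.  ``metabolic`` defaults
    to the annotation's ``is_metabolic`` genes of each cohort.
    """
    per_cohort: dict[str, pd.DataFrame] = {}
    for cohort in cohorts:
        if cohort.normal_expr is None:
            raise ValueError(f"cohort {cohort.name!r} has no normal expression")
        de = differential_expression(cohort.tumour_expr, cohort.normal_expr)
        if metabolic is None:
            universe = cohort.annotation.loc[cohort.annotation["is_metabolic"], "gene_id"]
        else:
            universe = metabolic
        selected = top_decile_overexpressed(
            de, universe, use_q=use_q, fc_min=fc_min, q_max=q_max_de, fraction=top_fraction
        )
        per_cohort[cohort.name] = candidate_drivers(
            cohort, sorted(selected), gain_min=gain_min, rho_min=rho_min, q_max=q_max_rho, de=de
        )
    return per_cohort, core_signature(per_cohort, min_cancers=min_cancers)
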