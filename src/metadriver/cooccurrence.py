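"""Pairwise amplification co-occurrence and cytoband proximity clustering.

For each gene pair a 2x2 table is built over samples with non-missing calls
for both genes: both amplified / only one / neither.  "Amplified" means call
>= 1 when gains and amplifications are merged into one category (cohorts
whose calling does not separate them), or call == 2 otherwise.  Fisher's
exact test (two-sided, probability-mass rule) scores each pair.

Proximity clusters group candidate genes and anchor genes (e.g. known
amplified oncogenes) that sit on the same chromosome arm in adjacent
cytobands and whose pairwise gains significantly co-occur — the synthetic
analogue of a co-amplified amplicon such as 8q24.
"""

from __future__ import annotations

import re
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust


def build_2x2(calls_a, calls_b, merged: bool = True) -> np.ndarray:
    """2x2 amplification co-occurrence table for two genes' call vectors.

    Rows index gene a (amplified / not), columns gene b; only samples with
    non-missing calls for both genes are counted.
    """
    a = np.asarray(calls_a, dtype=float)
    b = np.asarray(calls_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("call vectors must have equal length")
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    amp_a = a >= 1 if merged else a == 2
    amp_b = b >= 1 if merged else b == 2
    return np.array(
        [
            [int((amp_a & amp_b).sum()), int((amp_a & ~amp_b).sum())],
            [int((~amp_a & amp_b).sum()), int((~amp_a & ~amp_b).sum())],
        ]
    )


def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    The two-sided p sums the probabilities of all margin-fixed tables at
    most as probable as the observed one.  The odds ratio is the sample
    (unconditional) estimate, with 0/inf conventions for zero cells.
    """
    table = np.asarray(table)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    a, b = table[0]
    c, d = table[1]
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = a * d / (b * c)
    return float(odds), float(p)


def pairwise_cooccurrence(
    calls: pd.DataFrame,
    genes_a: Iterable[str],
    genes_b: Iterable[str] | None = None,
    merged: bool = True,
    bh: bool = False,
) -> pd.DataFrame:
    """Fisher co-occurrence tests for all pairs between two gene lists.

    With ``genes_b`` omitted, all unordered pairs within ``genes_a`` are
    tested.  Raw p-values are reported by default; ``bh=True`` adds a
    BH-adjusted column across the tested pairs.
    """
    genes_a = [g for g in genes_a if g in calls.index]
    if genes_b is None:
        pairs = [(a, b) for i, a in enumerate(genes_a) for b in genes_a[i + 1 :]]
    else:
        genes_b = [g for g in genes_b if g in calls.index]
        pairs = [(a, b) for a in genes_a for b in genes_b if a != b]
    rows = []
    for a, b in pairs:
        table = build_2x2(calls.loc[a], calls.loc[b], merged=merged)
        odds, p = fisher_exact(table)
        rows.append((a, b, table[0, 0], table[0, 1], table[1, 0], table[1, 1], odds, p))
    out = pd.DataFrame(
        rows,
        columns=["gene_a", "gene_b", "both", "only_a", "only_b", "neither", "odds_ratio", "p"],
    )
    if bh and len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
    return out


_BAND_RE = re.compile(r"^([pq])(\d+)")


def _parse_band(cytoband: str) -> tuple[str, int] | None:
    m = _BAND_RE.match(cytoband)
    if m is None:
        return None
    return m.group(1), int(m.group(2))


def band_proximity_clusters(
    candidates: Iterable[str],
    anchors: Iterable[str],
    ann: pd.DataFrame,
    results: pd.DataFrame,
    alpha: float = 0.05,
    max_band_gap: int = 1,
) -> list[dict]:
    """Clusters of co-gained genes in proximal cytobands.

    Two genes are proximal when they share a chromosome arm and their band
    indices differ by at most ``max_band_gap``.  Proximal pairs whose
    co-occurrence p (from ``results``, either gene order) falls below
    ``alpha`` are linked; connected components of two or more genes are
    returned with members and the minimum pairwise p.  Genes without usable
    annotation are skipped.
    """
    genes = sorted(set(candidates) | set(anchors))
    info = {}
    ann_idx = ann.set_index("gene_id")
    for g in genes:
        if g not in ann_idx.index:
            continue
        band = _parse_band(str(ann_idx.loc[g, "cytoband"]))
        if band is None:
            continue
        info[g] = (str(ann_idx.loc[g, "chromosome"]), band[0], band[1])
    pvals: dict[tuple[str, str], float] = {}
    for _, row in results.iterrows():
        key = tuple(sorted((row["gene_a"], row["gene_b"])))
        pvals[key] = min(pvals.get(key, np.inf), row["p"])
    graph = nx.Graph()
    graph.add_nodes_from(info)
    items = sorted(info)
    for i, a in enumerate(items):
        for b in items[i + 1 :]:
            ca, arma, banda = info[a]
            cb, armb, bandb = info[b]
            if ca != cb or arma != armb or abs(banda - bandb) > max_band_gap:
                continue
            p = pvals.get((a, b) if a < b else (b, a))
            if p is not None and p < alpha:
                graph.add_edge(a, b, p=p)
    clusters = []
    for comp in nx.connected_components(graph):
        if len(comp) < 2:
            continue
        members = sorted(comp)
        min_p = min(graph.edges[e]["p"] for e in graph.subgraph(comp).edges)
        clusters.append({"genes": members, "min_p": float(min_p)})
    clusters.sort(key=lambda c: c["genes"])
    return clusters
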