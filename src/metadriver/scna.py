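"""Discrete somatic copy-number calls from log2 ratios and altered-fraction summaries.

Calls use the five-state alphabet {-2, -1, 0, 1, 2}: homozygous deletion,
heterozygous loss, neutral, gain, amplification.  The thresholds on the
log2 ratio ``t`` are::

    t >  1            ->  2   (amplification)
    0.2 <= t <= 1     ->  1   (gain)
    -0.2 <  t <  0.2  ->  0   (neutral)
    -1   <= t <= -0.2 -> -1   (loss)
    t < -1            -> -2   (homozygous deletion)

Both 0.2 boundaries are inclusive on the altered side, as are the +/-1
boundaries on the gain/loss side; missing ratios propagate to missing calls.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

GAIN_THRESHOLD = 0.2
AMP_THRESHOLD = 1.0
LOSS_THRESHOLD = -0.2
HOMDEL_THRESHOLD = -1.0


def call_scna(t):
    """Map log2 ratio(s) to discrete SCNA call(s).

    Accepts a scalar, array or DataFrame; NaN maps to NaN, any other
    non-finite value raises.
    """
    if isinstance(t, pd.DataFrame):
        values = call_scna(t.to_numpy())
        return pd.DataFrame(values, index=t.index, columns=t.columns)
    arr = np.asarray(t, dtype=float)
    if np.isinf(arr).any():
        raise ValueError("non-finite log2 ratio")
    calls = np.zeros(arr.shape, dtype=float)
    calls[arr > AMP_THRESHOLD] = 2
    calls[(arr >= GAIN_THRESHOLD) & (arr <= AMP_THRESHOLD)] = 1
    calls[(arr <= LOSS_THRESHOLD) & (arr >= HOMDEL_THRESHOLD)] = -1
    calls[arr < HOMDEL_THRESHOLD] = -2
    calls[np.isnan(arr)] = np.nan
    if np.isscalar(t) or arr.ndim == 0:
        v = float(calls)
        return v if np.isnan(v) else int(v)
    return calls


def merge_gain_amp(calls: pd.DataFrame) -> pd.DataFrame:
    """Collapse amplifications into gains (2 -> 1); other states unchanged.

    Matches cohorts whose copy-number calling does not separate the two
    categories (e.g. Metabric-style calls); idempotent.
    """
    out = calls.copy()
    out[out == 2] = 1
    return out


def altered_fractions(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-gene gained and loss fractions over non-missing calls.

    Gained counts calls {1, 2}; loss counts {-1, -2}.  Genes with no
    non-missing call get missing fractions.
    """
    arr = calls.to_numpy(dtype=float)
    valid = ~np.isnan(arr)
    n = valid.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        gained = np.where(n > 0, np.nansum(arr >= 1, axis=1) / np.where(n > 0, n, 1), np.nan)
        loss = np.where(n > 0, np.nansum(arr <= -1, axis=1) / np.where(n > 0, n, 1), np.nan)
    gained[n == 0] = np.nan
    loss[n == 0] = np.nan
    return pd.DataFrame(
        {"gained_fraction": gained, "loss_fraction": loss},
        index=calls.index.rename("gene_id"),
    )


def geneset_instability(calls: pd.DataFrame, genes: Iterable[str]) -> tuple[float, float]:
    """Cohort-level instability of a gene set.

    Unweighted mean of the per-gene gained and loss fractions over the set;
    an estimate of the fraction of the cohort altered for those genes.
    """
    genes = [g for g in genes if g in calls.index]
    if not genes:
        raise ValueError("empty gene set")
    frac = altered_fractions(calls.loc[genes])
    return float(frac["gained_fraction"].mean()), float(frac["loss_fraction"].mean())


def per_sample_gained_fraction(calls: pd.DataFrame, genes: Iterable[str]) -> pd.Series:
    """Per-sample fraction of the gene set with call >= 1 (gain or amplification)."""
    genes = [g for g in genes if g in calls.index]
    if not genes:
        raise ValueError("empty gene set")
    arr = calls.loc[genes].to_numpy(dtype=float)
    valid = ~np.isnan(arr)
    n = valid.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.nansum(arr >= 1, axis=0) / np.where(n > 0, n, np.nan)
    return pd.Series(frac, index=calls.columns, name="gained_fraction")
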