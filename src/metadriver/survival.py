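"""Univariate and repeated-split multivariate prognostic modelling.

The univariate layer follows the common clinical-genomics recipe:
follow-up truncation, median dichotomisation of a gene's expression into
high/low risk groups, Cox hazard ratio with Wald test, and the log-rank
test.  The multivariate layer pre-selects genes on the training half by a
log-rank screen (P < 0.1), then fits an L1-penalised (LASSO) proportional-
hazards model on continuous expression with the penalty chosen by k-fold
cross-validated partial-likelihood deviance; clinical covariates (age
dichotomised at 50, ordinal stage) can be included unpenalised.  Repeated
random splits yield a held-out concordance distribution and per-gene
inclusion frequencies.

Records are a DataFrame indexed by sample id with ``time`` (years) and
``event`` (bool) columns plus one column per covariate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.utils import concordance_index
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .io_core import CohortBundle

CLINICAL_FEATURES = ["age_ge_50", "stage"]


@dataclass
class UnivariateCoxResult:
    hr: float
    ci95: tuple[float, float]
    wald_p: float
    separation: bool = False


@dataclass
class PrognosticModel:
    selected_features: dict[str, float]
    clinical_features: dict[str, float]
    training_ids: list[str]
    cv_error_curve: pd.Series
    chosen_penalty: float
    feature_names: list[str] = field(default_factory=list)
    coef: np.ndarray = field(default_factory=lambda: np.zeros(0))
    center: np.ndarray = field(default_factory=lambda: np.zeros(0))
    scale: np.ndarray = field(default_factory=lambda: np.ones(0))

    def predict_risk(self, records: pd.DataFrame) -> pd.Series:
        """Linear predictor (log relative hazard) for new samples."""
        if not self.feature_names:
            return pd.Series(0.0, index=records.index, name="risk")
        x = records[self.feature_names].to_numpy(dtype=float)
        x = (x - self.center) / self.scale
        return pd.Series(x @ self.coef, index=records.index, name="risk")


# ---------------------------------------------------------------------------
# record assembly and univariate machinery


def build_survival_records(cohort: CohortBundle, genes: Sequence[str]) -> pd.DataFrame:
    """Survival records for a cohort: time/event, clinical covariates, gene expression."""
    clin = cohort.clinical.set_index("sample_id")
    samples = [s for s in cohort.tumour_expr.columns if s in clin.index]
    records = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    records["time"] = clin.loc[samples, "time_years"].astype(float)
    records["event"] = clin.loc[samples, "event"].astype(bool)
    records["age_ge_50"] = (clin.loc[samples, "age"] >= 50).astype(float)
    records["stage"] = clin.loc[samples, "stage"].astype(float)
    genes = [g for g in genes if g in cohort.tumour_expr.index]
    records[genes] = cohort.tumour_expr.loc[genes, samples].T.to_numpy()
    return records


def truncate_followup(records: pd.DataFrame, cutoff_years: float) -> pd.DataFrame:
    """Administratively censor follow-up beyond the cutoff.

    Times strictly above the cutoff become the cutoff with the event flag
    cleared; a time exactly at the cutoff is left untouched.
    """
    if cutoff_years < 0:
        raise ValueError("cutoff must be non-negative")
    out = records.copy()
    over = out["time"] > cutoff_years
    out.loc[over, "time"] = cutoff_years
    out.loc[over, "event"] = False
    return out


def median_dichotomise(values) -> np.ndarray:
    """Split at the median: value > median is "high", <= median "low"."""
    v = np.asarray(values, dtype=float)
    if np.all(v == v[0]):
        raise ValueError("constant vector cannot be dichotomised")
    return np.where(v > np.median(v), "high", "low")


def quartile_groups(values) -> np.ndarray:
    """Four groups at the 25th/50th/75th percentiles; boundary ties go low."""
    v = np.asarray(values, dtype=float)
    p25, p50, p75 = np.percentile(v, [25, 50, 75])
    labels = np.where(v <= p25, "Q1", np.where(v <= p50, "Q2", np.where(v <= p75, "Q3", "Q4")))
    if len(np.unique(labels)) < 4:
        raise ValueError("too few distinct values for four non-empty groups")
    return labels


def logrank(groups, time, event) -> float:
    """Two-group log-rank test p-value (chi-square with 1 df).

    Uses the standard hypergeometric variance with the tie correction
    ``(n - d) / (n - 1)`` at each distinct event time.
    """
    groups = np.asarray(groups)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError("log-rank test requires exactly two groups")
    in_a = groups == labels[0]
    event_times = np.unique(time[event])
    o = e = v = 0.0
    for t in event_times:
        at_risk = time >= t
        n = at_risk.sum()
        n_a = (at_risk & in_a).sum()
        d = (event & (time == t)).sum()
        d_a = (event & (time == t) & in_a).sum()
        o += d_a
        e += d * n_a / n
        if n > 1:
            v += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if v == 0:
        return 1.0
    chi2 = (o - e) ** 2 / v
    return float(stats.chi2.sf(chi2, 1))


def univariate_cox(groups, time, event) -> UnivariateCoxResult:
    """Hazard ratio of the "high" group vs the "low" group with Wald test.

    Complete separation (monotone likelihood) is flagged rather than raised.
    """
    event = np.asarray(event, dtype=bool)
    if not event.any():
        raise ValueError("no events in the data")
    df = pd.DataFrame(
        {
            "time": np.asarray(time, dtype=float),
            "event": event.astype(int),
            "high": (np.asarray(groups) == "high").astype(float),
        }
    )
    fitter = CoxPHFitter()
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        fitter.fit(df, duration_col="time", event_col="event")
        separation = any("convergence" in str(w.message).lower() for w in caught)
    row = fitter.summary.loc["high"]
    return UnivariateCoxResult(
        hr=float(np.exp(row["coef"])),
        ci95=(float(np.exp(row["coef lower 95%"])), float(np.exp(row["coef upper 95%"]))),
        wald_p=float(row["p"]),
        separation=separation,
    )


# ---------------------------------------------------------------------------
# penalised multivariate modelling


def cox_partial_loglik(time, event, scores) -> float:
    """Breslow partial log-likelihood of risk scores (linear predictors)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(time, kind="mergesort")
    time, event, scores = time[order], event[order], scores[order]
    # suffix log-sum-exp over the risk set {j : t_j >= t_i}
    shift = scores.max()
    rev_cumsum = np.cumsum(np.exp(scores - shift)[::-1])[::-1]
    log_denom = np.log(rev_cumsum) + shift
    # ties share the risk set of the first tied index
    first_idx = np.searchsorted(time, time, side="left")
    return float(np.sum(scores[event] - log_denom[first_idx][event]))


def _screen_genes(records: pd.DataFrame, gene_pool: Sequence[str], alpha: float) -> list[str]:
    survivors = []
    for gene in gene_pool:
        values = records[gene].to_numpy(dtype=float)
        if np.all(values == values[0]):
            continue
        groups = median_dichotomise(values)
        if logrank(groups, records["time"], records["event"]) < alpha:
            survivors.append(gene)
    return survivors


def train_multivariate(
    records: pd.DataFrame,
    gene_pool: Sequence[str],
    preselect_alpha: float = 0.1,
    n_folds: int = 10,
    clinical: bool = False,
    seed: int = 0,
    n_alphas: int = 30,
    penalty: float | None = None,
) -> PrognosticModel:
    """Pre-selection screen plus cross-validated LASSO proportional-hazards fit.

    Genes passing the median-dichotomised log-rank screen (training data
    only) enter an L1-penalised Cox model on continuous expression; the
    penalty grid is searched by stratified k-fold cross-validation of the
    held-out partial-likelihood deviance.  With ``clinical`` set, age >= 50
    and ordinal stage are included with zero penalty (never dropped).
    """
    events = records["event"].to_numpy(dtype=bool)
    if events.sum() < n_folds:
        raise ValueError(f"need >= {n_folds} events for {n_folds}-fold cross-validation")
    gene_pool = [g for g in gene_pool if g in records.columns]
    survivors = _screen_genes(records, gene_pool, preselect_alpha)
    clin_feats = [f for f in CLINICAL_FEATURES if f in records.columns] if clinical else []
    features = survivors + clin_feats
    training_ids = list(records.index)
    if not features:
        return PrognosticModel(
            selected_features={},
            clinical_features={},
            training_ids=training_ids,
            cv_error_curve=pd.Series(dtype=float),
            chosen_penalty=float("nan"),
        )
    x = records[features].to_numpy(dtype=float)
    center = x.mean(axis=0)
    scale = x.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    xs = (x - center) / scale
    y = Surv.from_arrays(event=events, time=records["time"].to_numpy(dtype=float))
    penalty_factor = np.array([0.0 if f in clin_feats else 1.0 for f in features])
    if penalty_factor.sum() == 0:
        # clinical-only model: a single effectively unpenalised fit
        penalty_factor = None
        alphas = np.array([1e-9])
    elif penalty is not None:
        alphas = np.array([penalty])
    else:
        path = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, n_alphas=n_alphas, penalty_factor=penalty_factor, alpha_min_ratio=0.01
        )
        path.fit(xs, y)
        alphas = np.asarray(path.alphas_)
    if alphas.size > 1:
        folds = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        deviance = np.zeros(alphas.size)
        weight = np.zeros(alphas.size)
        for train_idx, test_idx in folds.split(xs, events):
            est = CoxnetSurvivalAnalysis(
                l1_ratio=1.0, alphas=alphas, penalty_factor=penalty_factor
            )
            est.fit(xs[train_idx], y[train_idx])
            n_ev = events[test_idx].sum()
            if n_ev == 0:
                continue
            for k, alpha in enumerate(est.alphas_):
                coef = est.coef_[:, k]
                scores = xs[test_idx] @ coef
                deviance[k] += -2.0 * cox_partial_loglik(
                    records["time"].to_numpy()[test_idx], events[test_idx], scores
                )
                weight[k] += 1
        cv_curve = pd.Series(deviance / np.maximum(weight, 1), index=alphas, name="cv_deviance")
        chosen = float(cv_curve.idxmin())
    else:
        cv_curve = pd.Series([np.nan], index=alphas, name="cv_deviance")
        chosen = float(alphas[0])
    final = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[chosen], penalty_factor=penalty_factor)
    with warnings.catch_warnings():
        # an all-zero coefficient vector is a legitimate outcome at strong penalties
        warnings.filterwarnings("ignore", message="all coefficients are zero")
        final.fit(xs, y)
    coef = final.coef_[:, 0]
    selected = {
        f: float(c) for f, c in zip(features, coef) if c != 0 and f not in clin_feats
    }
    clinical_coefs = {f: float(c) for f, c in zip(features, coef) if f in clin_feats}
    return PrognosticModel(
        selected_features=selected,
        clinical_features=clinical_coefs,
        training_ids=training_ids,
        cv_error_curve=cv_curve,
        chosen_penalty=chosen,
        feature_names=features,
        coef=coef,
        center=center,
        scale=scale,
    )


def concordance(model: PrognosticModel, records: pd.DataFrame) -> float:
    """Harrell's concordance index of predicted risk against observed survival.

    Higher risk should pair with earlier failure; ties in risk contribute
    0.5.  Raises when no comparable pair exists.
    """
    risk = model.predict_risk(records).to_numpy()
    return concordance_from_risk(records["time"], records["event"], risk)


def concordance_from_risk(time, event, risk) -> float:
    event = np.asarray(event, dtype=bool)
    if not event.any():
        raise ValueError("no usable pairs: no events observed")
    try:
        return float(
            concordance_index(np.asarray(time, dtype=float), -np.asarray(risk, dtype=float), event)
        )
    except ZeroDivisionError as err:
        raise ValueError("no usable pairs under censoring") from err


def repeated_split_evaluation(
    records: pd.DataFrame,
    gene_pool: Sequence[str],
    n_repeats: int = 1000,
    train_fraction: float = 0.5,
    external: pd.DataFrame | None = None,
    preselect_alpha: float = 0.1,
    n_folds: int = 10,
    clinical: bool = False,
    inclusion_threshold: float = 0.2,
    seed: int = 0,
) -> dict:
    """Repeated random-split training with held-out concordance.

    Each repeat redraws an event-stratified train/validation split
    (``train_fraction`` in training; 2:1 splits use 2/3), trains the
    penalised model on the training part and scores concordance on the
    held-out part (and on an external cohort if supplied).  Inclusion
    frequency is the fraction of repeats selecting each gene; genes above
    ``inclusion_threshold`` are reported separately.
    """
    rng = np.random.default_rng(seed)
    events = records["event"].to_numpy(dtype=bool)
    idx_event = np.flatnonzero(events)
    idx_censor = np.flatnonzero(~events)
    c_values = np.full(n_repeats, np.nan)
    c_external = np.full(n_repeats, np.nan) if external is not None else None
    counts: dict[str, int] = {}
    for r in range(n_repeats):
        train_idx = np.concatenate(
            [
                rng.choice(idx_event, size=max(1, int(round(train_fraction * idx_event.size))), replace=False),
                rng.choice(idx_censor, size=int(round(train_fraction * idx_censor.size)), replace=False),
            ]
        )
        mask = np.zeros(len(records), dtype=bool)
        mask[train_idx] = True
        train, test = records.iloc[mask], records.iloc[~mask]
        model = train_multivariate(
            train,
            gene_pool,
            preselect_alpha=preselect_alpha,
            n_folds=n_folds,
            clinical=clinical,
            seed=int(rng.integers(2**31 - 1)),
        )
        for gene in model.selected_features:
            counts[gene] = counts.get(gene, 0) + 1
        c_values[r] = concordance(model, test)
        if external is not None:
            c_external[r] = concordance(model, external)
    inclusion = pd.Series(
        {g: counts.get(g, 0) / n_repeats for g in gene_pool}, name="inclusion_frequency"
    ).sort_values(ascending=False)
    result = {
        "c_index": c_values,
        "inclusion_frequency": inclusion,
        "frequent_genes": inclusion[inclusion > inclusion_threshold],
    }
    if external is not None:
        result["c_index_external"] = c_external
    return result


def refit_frequent_genes(
    records: pd.DataFrame,
    inclusion: pd.Series,
    threshold: float = 0.2,
    clinical: bool = False,
    n_folds: int = 10,
    seed: int = 0,
) -> PrognosticModel:
    """Final classifier refit on the full cohort with the frequently selected genes."""
    genes = list(inclusion.index[inclusion > threshold])
    return train_multivariate(
        records, genes, preselect_alpha=1.1, n_folds=n_folds, clinical=clinical, seed=seed
    )
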