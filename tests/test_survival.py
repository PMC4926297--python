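import dataclasses

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test

from metadriver.survival import (
    build_survival_records,
    concordance,
    concordance_from_risk,
    cox_partial_loglik,
    logrank,
    median_dichotomise,
    quartile_groups,
    repeated_split_evaluation,
    train_multivariate,
    truncate_followup,
    univariate_cox,
)
from metadriver.synthetic_cohort import simulate_cohort


def _records(time, event, **covariates):
    df = pd.DataFrame({"time": time, "event": event})
    for name, values in covariates.items():
        df[name] = values
    df.index = pd.Index([f"s{i}" for i in range(len(df))], name="sample_id")
    return df


class TestTruncateFollowup:
    def test_event_beyond_cutoff_becomes_censored_at_cutoff(self):
        rec = _records([12.0], [True])
        out = truncate_followup(rec, 10.0)
        assert out["time"].iloc[0] == 10.0
        assert not out["event"].iloc[0]

    def test_event_within_cutoff_unchanged(self):
        rec = _records([4.0], [True])
        out = truncate_followup(rec, 5.0)
        assert out["time"].iloc[0] == 4.0 and out["event"].iloc[0]

    def test_boundary_time_not_truncated(self):
        rec = _records([10.0], [True])
        out = truncate_followup(rec, 10.0)
        assert out["time"].iloc[0] == 10.0 and out["event"].iloc[0]

    def test_negative_cutoff_raises(self):
        with pytest.raises(ValueError):
            truncate_followup(_records([1.0], [True]), -1.0)


class TestGrouping:
    def test_median_split(self):
        labels = median_dichotomise([1, 2, 3, 4])
        assert list(labels) == ["low", "low", "high", "high"]

    def test_ties_at_median_go_low(self):
        labels = median_dichotomise([1, 2, 2, 3])
        assert list(labels) == ["low", "low", "low", "high"]

    def test_two_distinct_values(self):
        assert list(median_dichotomise([1, 5])) == ["low", "high"]

    def test_constant_vector_raises(self):
        with pytest.raises(ValueError):
            median_dichotomise([2, 2, 2])

    def test_quartiles_of_one_to_eight(self):
        labels = quartile_groups(np.arange(1, 9))
        _, counts = np.unique(labels, return_counts=True)
        assert list(counts) == [2, 2, 2, 2]

    def test_quartile_sizes_balanced_for_distinct_values(self):
        labels = quartile_groups(np.random.default_rng(0).permutation(100))
        _, counts = np.unique(labels, return_counts=True)
        assert all(abs(c - 25) <= 1 for c in counts)

    def test_quartile_boundary_ties_go_low(self):
        values = [1, 2, 2, 3, 4, 5, 6, 7]  # p25 = 2: both 2s fall in Q1
        labels = quartile_groups(values)
        assert list(labels[:3]) == ["Q1", "Q1", "Q1"]
        _, counts = np.unique(labels, return_counts=True)
        assert list(counts) == [3, 1, 2, 2]

    def test_quartiles_with_too_few_distinct_values_raise(self):
        with pytest.raises(ValueError):
            quartile_groups([1, 1, 1, 2])


class TestLogrank:
    def test_identical_groups_give_p_one(self):
        time = [1, 2, 3, 4, 1, 2, 3, 4]
        event = [True] * 8
        groups = ["a"] * 4 + ["b"] * 4
        assert logrank(groups, time, event) == pytest.approx(1.0)

    def test_matches_lifelines_on_random_data(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            n = 40
            time = rng.exponential(5, n)
            event = rng.random(n) < 0.7
            groups = np.where(rng.random(n) < 0.5, "a", "b")
            expected = logrank_test(
                time[groups == "a"], time[groups == "b"],
                event[groups == "a"], event[groups == "b"],
            ).p_value
            assert logrank(groups, time, event) == pytest.approx(expected, rel=1e-6)

    def test_strong_effect_detected(self):
        rng = np.random.default_rng(2)
        n = 500
        groups = np.where(np.arange(n) < n // 2, "high", "low")
        rate = np.where(groups == "high", 0.4, 0.1)
        time = rng.exponential(1 / rate)
        assert logrank(groups, time, np.ones(n, dtype=bool)) < 0.001

    def test_single_group_raises(self):
        with pytest.raises(ValueError):
            logrank(["a", "a"], [1, 2], [True, True])


class TestUnivariateCox:
    def test_true_hazard_ratio_recovered(self):
        rng = np.random.default_rng(3)
        n = 1000
        groups = np.where(np.arange(n) < n // 2, "high", "low")
        rate = np.where(groups == "high", 0.2, 0.1)  # true HR = 2
        time = rng.exponential(1 / rate)
        res = univariate_cox(groups, time, np.ones(n, dtype=bool))
        assert 1.8 <= res.hr <= 2.2
        assert res.ci95[0] < res.hr < res.ci95[1]

    def test_label_swap_inverts_hazard_ratio(self):
        rng = np.random.default_rng(4)
        n = 200
        groups = np.where(rng.random(n) < 0.5, "high", "low")
        time = rng.exponential(5, n)
        event = rng.random(n) < 0.8
        res = univariate_cox(groups, time, event)
        swapped = np.where(groups == "high", "low", "high")
        res2 = univariate_cox(swapped, time, event)
        assert res.hr == pytest.approx(1 / res2.hr, rel=1e-6)
        assert res.wald_p == pytest.approx(res2.wald_p, rel=1e-6)

    def test_no_events_raise(self):
        with pytest.raises(ValueError):
            univariate_cox(["high", "low"], [1.0, 2.0], [False, False])


def brute_force_partial_loglik(time, event, scores):
    ll = 0.0
    for i in range(len(time)):
        if not event[i]:
            continue
        risk_set = [j for j in range(len(time)) if time[j] >= time[i]]
        ll += scores[i] - np.log(sum(np.exp(scores[j]) for j in risk_set))
    return ll


def test_partial_loglik_matches_brute_force():
    rng = np.random.default_rng(5)
    for _ in range(5):
        n = 25
        time = rng.exponential(3, n).round(1)  # rounding creates ties
        event = rng.random(n) < 0.7
        scores = rng.normal(size=n)
        got = cox_partial_loglik(time, event, scores)
        assert got == pytest.approx(brute_force_partial_loglik(time, event, scores), rel=1e-10)


def brute_force_concordance(time, event, risk):
    """Harrell's definition by explicit pair enumeration.

    A pair is comparable when the earlier time is an event, or when the
    times tie and exactly one is an event (the event precedes the censored
    observation); tied event times are not comparable.  Risk ties score 0.5.
    """
    num = den = 0.0
    n = len(time)
    for i in range(n):
        for j in range(n):
            if not event[i]:
                continue
            if time[i] < time[j] or (time[i] == time[j] and not event[j]):
                den += 1
                if risk[i] > risk[j]:
                    num += 1
                elif risk[i] == risk[j]:
                    num += 0.5
    return num / den


class TestConcordance:
    def test_perfect_and_reversed_risk(self):
        time = np.array([5.0, 3.0, 9.0, 1.0])
        event = np.ones(4, dtype=bool)
        risk = -time  # earlier failure = higher risk
        assert concordance_from_risk(time, event, risk) == 1.0
        assert concordance_from_risk(time, event, -risk) == 0.0

    def test_matches_pair_enumeration_under_censoring(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            n = 30
            time = rng.exponential(3, n).round(1)
            event = rng.random(n) < 0.6
            risk = rng.normal(size=n)
            if not event.any():
                continue
            got = concordance_from_risk(time, event, risk)
            assert got == pytest.approx(brute_force_concordance(time, event, risk), rel=1e-12)

    def test_random_risk_near_half(self):
        rng = np.random.default_rng(7)
        cs = []
        for seed in range(20):
            time = rng.exponential(3, 200)
            event = rng.random(200) < 0.7
            cs.append(concordance_from_risk(time, event, rng.normal(size=200)))
        assert 0.45 < np.median(cs) < 0.55

    def test_no_events_raise(self):
        with pytest.raises(ValueError):
            concordance_from_risk([1.0, 2.0], [False, False], [0.3, 0.1])


@pytest.fixture(scope="module")
def planted_records(small_params_module=None):
    from metadriver.synthetic_cohort import SimulationParams

    params = SimulationParams(
        n_tumour=400, n_normal=20, n_genes=150, n_chromosomes=4,
        n_planted_drivers=5, n_signature_genes=8, n_hypoxia_coupled_drivers=2,
        n_prognostic_genes=3, prognostic_beta=0.8, seed=21,
    )
    bundle, truth = simulate_cohort(params, 0)
    prognostic = sorted(truth.prognostic)
    noise = [g for g in bundle.tumour_expr.index
             if g not in truth.prognostic and g not in truth.planted_drivers][:27]
    pool = prognostic + noise
    records = truncate_followup(build_survival_records(bundle, pool), 10.0)
    return records, pool, prognostic


class TestTrainMultivariate:
    def test_recovers_planted_genes_and_is_deterministic(self, planted_records):
        records, pool, prognostic = planted_records
        m1 = train_multivariate(records, pool, seed=3)
        m2 = train_multivariate(records, pool, seed=3)
        assert set(prognostic) <= set(m1.selected_features)
        assert m1.selected_features == m2.selected_features
        assert m1.chosen_penalty == m2.chosen_penalty
        assert m1.chosen_penalty == m1.cv_error_curve.idxmin()

    def test_infinite_penalty_keeps_only_clinical_covariates(self, planted_records):
        records, pool, _ = planted_records
        model = train_multivariate(records, pool, clinical=True, penalty=1e6, seed=0)
        assert model.selected_features == {}
        assert set(model.clinical_features) == {"age_ge_50", "stage"}

    def test_empty_screen_gives_clinical_only_model(self, planted_records):
        records, pool, _ = planted_records
        model = train_multivariate(records, pool, preselect_alpha=1e-12, clinical=True, seed=0)
        assert model.selected_features == {}
        assert set(model.clinical_features) == {"age_ge_50", "stage"}
        model2 = train_multivariate(records, pool, preselect_alpha=1e-12, clinical=False, seed=0)
        assert model2.feature_names == []
        # featureless model predicts constant risk
        assert (model2.predict_risk(records) == 0).all()

    def test_too_few_events_raise(self, planted_records):
        records, pool, _ = planted_records
        few = records.iloc[:12]
        with pytest.raises(ValueError):
            train_multivariate(few, pool, n_folds=10)


class TestRepeatedSplit:
    def test_planted_signal_validates_out_of_sample(self, planted_records):
        records, pool, prognostic = planted_records
        result = repeated_split_evaluation(records, pool, n_repeats=20, seed=9)
        assert np.median(result["c_index"]) >= 0.65
        for gene in prognostic:
            assert result["inclusion_frequency"][gene] > 0.2
        assert set(result["frequent_genes"].index) >= set(prognostic)

    def test_external_cohort_scored(self, planted_records):
        records, pool, _ = planted_records
        half = len(records) // 2
        result = repeated_split_evaluation(
            records.iloc[:half], pool, n_repeats=5, external=records.iloc[half:], seed=4
        )
        assert np.isfinite(result["c_index_external"]).all()
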