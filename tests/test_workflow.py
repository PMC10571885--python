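"""Splits, TPE search, bootstrap evaluation, and the nested benchmark."""

import numpy as np
import pytest

from ndeepsurv import (ModelSpec, OptimizerConfig, SearchSpace,
                       SimulationConfig, concordance_index,
                       cross_validated_benchmark, hyperparameter_search,
                       repeated_test_evaluation, sample_validation,
                       simulate_cohort, split_train_test, stratified_folds,
                       train_model)
from ndeepsurv.models import TrainedModel
from ndeepsurv.workflow import SplitError


def make_cohort(n=1000, rate=0.05, seed=0, d=4, beta=None):
    cfg = SimulationConfig(n=n, d=d, beta=beta, baseline_rate=rate,
                           followup_years=10, seed=seed)
    return simulate_cohort(cfg)[0]


class TestSplits:
    def test_four_to_one_ratio_disjoint_exhaustive(self):
        ds = make_cohort(n=100, rate=0.2)
        tr, te = split_train_test(ds, ratio=0.2, seed=1)
        assert (tr.n, te.n) == (80, 20)
        assert set(tr.subject_ids) | set(te.subject_ids) == set(ds.subject_ids)
        assert not set(tr.subject_ids) & set(te.subject_ids)

    def test_event_stratification_at_low_rate(self):
        ds = make_cohort(n=1000, rate=0.0023)  # ~2% events at horizon
        overall = ds.E.mean()
        tr, te = split_train_test(ds, seed=2)
        for part in (tr, te):
            assert abs(part.E.mean() - overall) < 0.5 * overall + 1e-9

    def test_reproducible_by_seed(self):
        ds = make_cohort(n=200, rate=0.1)
        a = split_train_test(ds, seed=5)[1].subject_ids
        b = split_train_test(ds, seed=5)[1].subject_ids
        assert np.array_equal(a, b)

    def test_validation_sampling_sizes(self):
        ds = make_cohort(n=100, rate=0.3)
        tr, _ = split_train_test(ds, seed=1)
        sub, val = sample_validation(tr, p=0.2, seed=1)
        assert (sub.n, val.n) == (64, 16)

    def test_p_zero_warns_and_returns_empty_validation(self, caplog):
        ds = make_cohort(n=100, rate=0.3)
        with caplog.at_level("WARNING"):
            sub, val = sample_validation(ds, p=0.0)
        assert val.n == 0 and sub.n == ds.n

    def test_eventless_data_raises_split_error(self):
        ds = make_cohort(n=50, rate=0.2)
        ds.E[:] = 0
        with pytest.raises(SplitError):
            split_train_test(ds, seed=0)

    def test_folds_partition_rows(self):
        ds = make_cohort(n=103, rate=0.2)
        folds = stratified_folds(ds, 5, seed=3)
        all_idx = np.sort(np.concatenate(folds))
        assert np.array_equal(all_idx, np.arange(103))


class TestHyperparameterSearch:
    def test_tpe_concentrates_on_unimodal_optimum(self):
        space = SearchSpace({"x": ("uniform", 0.0, 10.0)})
        best, trials = hyperparameter_search(
            space, lambda p: -(p["x"] - 7.3) ** 2, n_trials=60, seed=4)
        assert abs(best["x"] - 7.3) < 1.0  # within the top decile of the range
        assert len([t for t in trials if t.state == "ok"]) == 60

    def test_single_trial_returns_that_draw(self):
        space = SearchSpace({"x": ("uniform", 0.0, 1.0)})
        best, trials = hyperparameter_search(space, lambda p: p["x"],
                                             n_trials=1, seed=5)
        assert best == trials[0].params

    def test_seeded_search_reproducible(self):
        space = SearchSpace({"lr": ("loguniform", 1e-4, 1e-1),
                             "width": ("int", 4, 64),
                             "act": ("choice", ["a", "b"])})
        f = lambda p: -abs(np.log10(p["lr"]) + 2) + p["width"] / 100
        a, _ = hyperparameter_search(space, f, n_trials=25, seed=6)
        b, _ = hyperparameter_search(space, f, n_trials=25, seed=6)
        assert a == b

    def test_failing_trials_skipped_all_failing_raises(self):
        space = SearchSpace({"x": ("uniform", 0.0, 1.0)})

        def bad(_):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="all 5 trials failed"):
            hyperparameter_search(space, bad, n_trials=5, seed=7)

    def test_invalid_space_rejected(self):
        with pytest.raises(ValueError):
            SearchSpace({"x": ("uniform", 1.0, 0.0)})
        with pytest.raises(ValueError):
            SearchSpace({"x": ("choice", [])})


class TestRepeatedEvaluation:
    def _fitted(self, ds, seed=0):
        return train_model(ModelSpec(kind="coxph"), ds, seed=seed)

    def test_identity_resample_gives_identical_values(self):
        ds = make_cohort(n=300, rate=0.1)
        m = self._fitted(ds)
        _, sd, values = repeated_test_evaluation(m, ds, "event", n_repeats=30,
                                                 seed=1, bootstrap=False)
        assert sd == pytest.approx(0.0, abs=1e-12)
        assert len(set(values)) == 1

    def test_bootstrap_mean_matches_replayed_resamples(self):
        ds = make_cohort(n=50, rate=0.3, seed=3)
        m = self._fitted(ds)
        mean, _, values = repeated_test_evaluation(m, ds, "event",
                                                   n_repeats=10, seed=9)
        # replay the seeded resample stream with an independent loop
        rng = np.random.default_rng(9)
        risk = m.predict_risk(ds, task="event")
        replayed = []
        for _ in range(10):
            idx = rng.integers(0, ds.n, size=ds.n)
            replayed.append(concordance_index(risk[idx], ds.T[idx],
                                              ds.E[idx, 0]))
        assert values == replayed
        assert mean == pytest.approx(np.mean(replayed))

    def test_same_seed_reproducible(self):
        ds = make_cohort(n=200, rate=0.1)
        m = self._fitted(ds)
        a = repeated_test_evaluation(m, ds, "event", seed=2)
        b = repeated_test_evaluation(m, ds, "event", seed=2)
        assert a[2] == b[2]


class _ConstantRisk(TrainedModel):
    def __init__(self, tasks):
        super().__init__(ModelSpec(kind="coxph"), tasks)

    def predict_risk(self, data, task=None):
        n = data.n if hasattr(data, "n") else len(data)
        return np.zeros(n)


def test_constant_risk_model_scores_exactly_chance():
    ds = make_cohort(n=400, rate=0.1)
    mean, sd, _ = repeated_test_evaluation(_ConstantRisk(["event"]), ds,
                                           "event", n_repeats=10, seed=0)
    assert mean == 0.5 and sd == 0.0


class TestBenchmark:
    def test_reduced_benchmark_report_shape(self):
        beta = np.zeros((3, 1))
        beta[0, 0] = 1.0
        ds = make_cohort(n=400, rate=0.05, d=3, beta=beta)
        report = cross_validated_benchmark(
            ds, [ModelSpec(kind="coxph")], folds=2, n_repeats=3, seed=0)
        assert len(report.records) == 2 * 3  # folds x repeats, one model/task
        assert set(report.records.columns) == {"model", "task", "fold",
                                               "repeat", "cindex"}
        summary = report.summary()
        assert summary.loc[0, "mean"] > 0.6  # signal present

    def test_benchmark_imputes_missing_from_train_side_only(self):
        ds = make_cohort(n=300, rate=0.1, d=3)
        rng = np.random.default_rng(0)
        ds.X[rng.random(ds.X.shape) < 0.05] = np.nan
        report = cross_validated_benchmark(
            ds, [ModelSpec(kind="coxph")], folds=2, n_repeats=2, seed=1)
        assert np.isfinite(report.records["cindex"]).all()
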