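"""Protocol: splits, training, metrics, repeated runs, greedy search, baselines."""

import numpy as np
import pytest

from soyield import (
    BaselineSpec,
    EvalResult,
    Metrics,
    ModelSpec,
    TrainConfig,
    build_stacked_lstm,
    evaluate,
    fit_baselines,
    mae_percent,
    split_records,
    train_model,
)
from soyield.errors import ConfigurationError, EvaluationError
from soyield.experiments import (
    GreedyStageError,
    greedy_search,
    greedy_weather_search,
    prediction_metrics,
)
from soyield.weatherprep import ModelInput


def toy_data(n=64, tx=4, d=3, seed=0, side_dim=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, tx, d))
    side = rng.normal(size=(n, side_dim))
    y = X[:, :, 0].mean(axis=1) + 0.1 * rng.normal(size=n)
    return ModelInput(X, side, y, y, [f"f{i}" for i in range(d)])


def test_split_sizes_disjoint_exhaustive_deterministic():
    tr, va, te = split_records(1000, (0.8, 0.1, 0.1), seed=3)
    assert (len(tr), len(va), len(te)) == (800, 100, 100)
    allidx = np.concatenate([tr, va, te])
    assert len(set(allidx)) == 1000
    tr2, va2, te2 = split_records(1000, (0.8, 0.1, 0.1), seed=3)
    assert np.array_equal(tr, tr2) and np.array_equal(va, va2) and np.array_equal(te, te2)
    with pytest.raises(ConfigurationError):
        split_records(2)
    with pytest.raises(ConfigurationError):
        split_records(100, (0.5, 0.2, 0.2))


def test_zero_learning_rate_leaves_parameters_unchanged():
    data = toy_data()
    spec = ModelSpec("stacked", tx=4, input_dim=3, hidden=4, dropout=0.0,
                     include_mg_cluster=False)
    m = build_stacked_lstm(spec, seed=0)
    before = {k: v.copy() for k, v in m.params.items()}
    train_model(m, data, TrainConfig(learning_rate=0.0, epochs=3, batch_size=16, seed=0))
    for k in before:
        assert np.array_equal(before[k], m.params[k])


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_training_reduces_loss(seed):
    data = toy_data(n=200, seed=seed)
    spec = ModelSpec("stacked", tx=4, input_dim=3, hidden=8, dropout=0.0,
                     include_mg_cluster=False)
    m = build_stacked_lstm(spec, seed=seed)
    hist = train_model(m, data, TrainConfig(epochs=25, batch_size=32, seed=seed))
    assert hist["train_loss"][-1] < hist["train_loss"][0]


def test_training_is_deterministic_given_seed():
    spec = ModelSpec("attention", tx=4, input_dim=3, hidden=4, include_mg_cluster=False)
    from soyield import build_temporal_attention

    h = []
    for _ in range(2):
        data = toy_data(n=96, seed=5)
        model = build_temporal_attention(spec, seed=7)
        h.append(train_model(model, data, TrainConfig(epochs=5, batch_size=32, seed=7)))
    assert h[0]["train_loss"] == h[1]["train_loss"]


def test_metric_hand_examples():
    m = prediction_metrics(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 4.0]))
    assert m.mae == pytest.approx(1.0 / 3.0)
    assert m.rmse == pytest.approx(np.sqrt(1.0 / 3.0))
    assert m.r2 == pytest.approx(0.5)  # SS_res = 1, SS_tot = 2
    exact = prediction_metrics(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
    assert (exact.rmse, exact.mae, exact.r2) == (0.0, 0.0, 1.0)
    y = np.array([1.0, 2.0, 3.0, 6.0])
    const = prediction_metrics(y, np.full(4, y.mean()))
    assert const.r2 == pytest.approx(0.0)
    with pytest.raises(EvaluationError):
        prediction_metrics(np.array([]), np.array([]))


def test_rmse_at_least_mae_property():
    rng = np.random.default_rng(0)
    for _ in range(25):
        n = int(rng.integers(2, 50))
        m = prediction_metrics(rng.normal(size=n), rng.normal(size=n))
        assert m.rmse >= m.mae >= 0.0


def test_repeated_runs_aggregation_conventions():
    res = EvalResult([Metrics(1.0, 1.0, 0.0), Metrics(2.0, 2.0, 0.0), Metrics(3.0, 3.0, 0.0)])
    assert res.mean("rmse") == pytest.approx(2.0)
    assert res.std("rmse") == pytest.approx(np.sqrt(2.0 / 3.0))  # population std
    assert res.summary()["std_convention"] == "population"
    single = EvalResult([Metrics(1.5, 1.0, 0.5)])
    assert single.std("mae") == 0.0


def test_mae_percent_printed_arithmetic():
    assert mae_percent(5.441, 50.745) == pytest.approx(10.72, abs=0.01)
    assert mae_percent(5.441, 16.019) == pytest.approx(33.96, abs=0.01)
    assert mae_percent(0.0, 10.0) == 0.0
    with pytest.raises(ConfigurationError):
        mae_percent(1.0, 0.0)


def test_greedy_single_candidate_and_structure():
    trace = greedy_search(["only"], lambda s: 1.0)
    assert trace.ranking == ["only"]
    calls = []

    def ev(subset):
        calls.append(subset)
        return float(len(subset))  # ties broken by candidate order

    trace = greedy_search(list("abcd"), ev)
    assert trace.ranking == list("abcd")
    assert len(calls) == 4 + 3 + 2 + 1
    assert [len(s.candidate_scores) for s in trace.stages] == [4, 3, 2, 1]


def test_greedy_failure_preserves_partial_trace():
    def ev(subset):
        if len(subset) == 2:
            raise EvaluationError("boom")
        return 1.0

    with pytest.raises(GreedyStageError) as err:
        greedy_search(["a", "b"], ev)
    assert err.value.stage == 2
    assert err.value.trace.ranking == ["a"]


def test_greedy_weather_trace_evaluates_28_models(bundle, clusters):
    cfg = TrainConfig(epochs=4, batch_size=256, seed=1)
    trace = greedy_weather_search(
        bundle.records, bundle.weather, clusters, "monthly", cfg,
        spec_kwargs={"hidden": 6}, include_mg_cluster=False,
    )
    assert sorted(trace.ranking) == sorted(
        ["ADNI", "AP", "ARH", "MDNI", "MaxSur", "MinSur", "AvgSur"]
    )
    assert sum(len(s.candidate_scores) for s in trace.stages) == 28
    assert [len(s.candidate_scores) for s in trace.stages] == [7, 6, 5, 4, 3, 2, 1]


def test_greedy_selects_signal_variable_and_matches_sweep(greedy_replicates):
    wins = sum(r["trace"].ranking[0] == "v2" for r in greedy_replicates)
    assert wins >= 9
    for r in greedy_replicates:
        stage1 = r["trace"].stages[0].candidate_scores
        greedy_order = sorted(r["names"], key=lambda v: stage1[v])
        sweep_order = sorted(r["names"], key=lambda v: r["sweep"][v])
        assert greedy_order == sweep_order


def test_lasso_recovers_linear_response():
    rng = np.random.default_rng(2)
    n, tx, d = 400, 3, 4
    X = rng.normal(size=(n, tx, d))
    w = rng.normal(size=tx * d)
    y = X.reshape(n, -1) @ w
    data = ModelInput(X, np.empty((n, 0)), y, y, [f"f{i}" for i in range(d)])
    tr, te = np.arange(300), np.arange(300, 400)

    class IdentityScaler:
        def inverse(self, z):
            return z

    res = fit_baselines(data.subset(tr), data.subset(te), IdentityScaler(),
                        BaselineSpec(lasso_alpha=1e-6), which=("lasso",))
    assert res["lasso"]["metrics"].r2 >= 0.99
    huge = fit_baselines(data.subset(tr), data.subset(te), IdentityScaler(),
                         BaselineSpec(lasso_alpha=1e6), which=("lasso",))
    assert huge["lasso"]["metrics"].r2 <= 1e-6  # collapses to the train intercept


def test_baseline_defaults_echoed_and_svr_runs(bundle, clusters):
    from soyield import assemble_inputs

    tr, va, te = split_records(len(bundle.records), seed=1)
    data, _, ysc = assemble_inputs(
        bundle.records, bundle.weather, clusters, granularity="monthly", train_idx=tr
    )
    res = fit_baselines(data.subset(tr), data.subset(te), ysc)
    assert res["svr"]["params"] == {"epsilon": 0.1, "C": 1.0, "kernel": "rbf"}
    assert res["lasso"]["params"]["alpha"] == pytest.approx(1e-6)
    for r in res.values():
        assert r["metrics"].rmse >= r["metrics"].mae
    # the planted surface is largely additive: both baselines beat the mean
    assert res["lasso"]["metrics"].r2 > 0.2
    assert res["svr"]["metrics"].r2 > 0.2
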