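"""Shared fixtures.

The expensive trained-model fixtures are session-scoped so the synthetic
recovery experiments (attention localization, paired architecture
comparison, greedy selection) are run once and shared across tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from soyield import (
    ModelSpec,
    SyntheticConfig,
    TrainConfig,
    assemble_inputs,
    build_stacked_lstm,
    build_temporal_attention,
    build_relationship_matrix,
    evaluate,
    generate_trial_bundle,
    kmeans_cluster,
    localization_score,
    repeated_runs,
    split_records,
    to_correlation,
    train_model,
)
from soyield.experiments import greedy_search, oracle_r2
from soyield.weatherprep import ModelInput

#: data seeds of the recovery experiments (fixed up front)
RECOVERY_SEEDS = (1, 2, 3)

#: weekly time-steps covered by the planted effect window, days 120-168
PLANTED_WINDOW_STEPS = (18, 24)


@pytest.fixture(scope="session")
def bundle():
    """The default desk-scale fixture bundle (seed 1)."""
    return generate_trial_bundle(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def clusters(bundle):
    """K-means cluster labels from pedigree relatedness, K = number of true families."""
    C = to_correlation(build_relationship_matrix(bundle.pedigree))
    return kmeans_cluster(C, bundle.config.n_clusters, seed=1).labels


@pytest.fixture(scope="session")
def recovery_runs():
    """Attention models trained on the planted fixture, one per data seed.

    Weekly granularity (Tx=30), MG+cluster inputs, hidden size 8, 200
    epochs -- the desk-scale interpretability configuration.
    """
    out = []
    for seed in RECOVERY_SEEDS:
        b = generate_trial_bundle(SyntheticConfig(seed=seed))
        tr, va, te = split_records(len(b.records), seed=seed)
        C = to_correlation(build_relationship_matrix(b.pedigree))
        labels = kmeans_cluster(C, b.config.n_clusters, seed=seed).labels
        data, _, ysc = assemble_inputs(
            b.records, b.weather, labels, granularity="weekly", train_idx=tr
        )
        model = build_temporal_attention(
            ModelSpec(variant="attention", tx=30, input_dim=9, hidden=8), seed=seed
        )
        train_model(model, data.subset(tr), TrainConfig(epochs=200, batch_size=256, seed=seed))
        profiles = model.attention_profiles(data.X, data.side)
        out.append(
            {
                "seed": seed,
                "bundle": b,
                "data": data,
                "model": model,
                "metrics": evaluate(model, data.subset(te), ysc),
                "oracle_r2": oracle_r2(b.truth, tr, te),
                "profiles": profiles,
                "localization": localization_score(profiles, PLANTED_WINDOW_STEPS),
            }
        )
    return out


@pytest.fixture(scope="session")
def paired_comparison(bundle, clusters):
    """Stacked-LSTM test RMSE with vs without MG+cluster inputs, 3 repeats
    on a fixed split (monthly granularity)."""
    tr, va, te = split_records(len(bundle.records), seed=1)
    cfg = TrainConfig(epochs=60, batch_size=256, n_repeats=3, seed=1)
    out = {}
    for include in (True, False):
        data, _, ysc = assemble_inputs(
            bundle.records, bundle.weather, clusters if include else None,
            granularity="monthly", include_mg_cluster=include, train_idx=tr,
        )
        spec = ModelSpec(
            variant="stacked", tx=7, input_dim=data.input_dim, hidden=16,
            include_mg_cluster=include,
        )
        out[include] = repeated_runs(
            lambda s: build_stacked_lstm(spec, seed=s),
            data.subset(tr), data.subset(te), ysc, cfg,
        )
    return out


def _greedy_signal_eval(rep: int):
    """Cheap stacked-LSTM criterion for a 3-variable toy where only v2
    carries signal; returns (names, evaluate_subset, test_rmse_by_var)."""
    rng = np.random.default_rng([123, rep])
    n, T = 300, 5
    V = rng.normal(size=(n, 3))
    y = 2.0 * V[:, 1] + 0.3 * rng.normal(size=n)
    X = np.repeat(V[:, None, :], T, axis=1)
    names = ["v1", "v2", "v3"]
    tr, te = np.arange(240), np.arange(240, 300)

    def evaluate_subset(subset):
        cols = [names.index(v) for v in subset]
        data = ModelInput(X[:, :, cols], np.empty((n, 0)), y, y, [names[c] for c in cols])
        spec = ModelSpec(
            variant="stacked", tx=T, input_dim=len(cols), hidden=6,
            dropout=0.0, include_mg_cluster=False,
        )
        m = build_stacked_lstm(spec, seed=rep)
        train_model(m, data.subset(tr), TrainConfig(epochs=30, batch_size=64, seed=rep))
        pred = m.predict(X[te][:, :, cols], np.empty((len(te), 0)))
        return float(np.sqrt(np.mean((pred - y[te]) ** 2)))

    return names, evaluate_subset


@pytest.fixture(scope="session")
def greedy_replicates():
    """Ten seeded replicates of stage-1 greedy selection on the toy with a
    single signal-bearing variable, plus an independent single-variable sweep."""
    results = []
    for rep in range(10):
        names, evaluate_subset = _greedy_signal_eval(rep)
        trace = greedy_search(names, evaluate_subset, n_stages=1)
        sweep = {v: evaluate_subset((v,)) for v in names}  # exhaustive 1-var sweep
        results.append({"trace": trace, "sweep": sweep, "names": names})
    return results
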