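"""Architectures: parameter accounting, attention mechanics, gradients."""

import numpy as np
import pytest

from soyield import (
    ModelSpec,
    attention_weights,
    build_stacked_lstm,
    build_temporal_attention,
    context_vector,
    count_trainable_params,
    expected_param_count,
)
from soyield.errors import ConfigurationError, FormatError


def _build(spec, seed=0):
    if spec.variant == "stacked":
        return build_stacked_lstm(spec, seed=seed)
    return build_temporal_attention(spec, seed=seed)


def test_reference_parameter_counts():
    stacked = ModelSpec("stacked", tx=30, input_dim=9, hidden=128, context_dim=2)
    attention = ModelSpec("attention", tx=30, input_dim=9, hidden=128, context_dim=2)
    weather_only = ModelSpec("stacked", tx=30, input_dim=7, hidden=128, context_dim=2,
                             include_mg_cluster=False)
    assert count_trainable_params(_build(stacked)) == 202_503
    assert count_trainable_params(_build(attention)) == 202_632
    assert count_trainable_params(_build(weather_only)) == 201_477
    # the scorer delta pins down a shared linear hidden->1 scorer with bias
    assert 202_632 - 202_503 == 128 + 1


def test_toy_hand_accounting():
    spec = ModelSpec("stacked", tx=3, input_dim=2, hidden=1, context_dim=1,
                     include_mg_cluster=False)
    assert count_trainable_params(_build(spec)) == 32  # 4*1*4 + 4*1*3 + 2 + 2


def test_parameter_counts_match_accounting_oracle_for_random_specs():
    rng = np.random.default_rng(17)
    for _ in range(20):
        spec = ModelSpec(
            variant=rng.choice(["stacked", "attention"]),
            tx=int(rng.integers(2, 40)),
            input_dim=int(rng.integers(1, 12)),
            hidden=int(rng.integers(1, 48)),
            context_dim=int(rng.integers(1, 6)),
            include_mg_cluster=bool(rng.integers(2)),
        )
        assert count_trainable_params(_build(spec)) == expected_param_count(spec)


def test_attention_weights_hand_examples():
    a = np.eye(2)  # two annotations of dim 2
    assert np.allclose(attention_weights(a[None, :1, :], np.zeros(2), 0.0), [[1.0]])
    # scores (0, ln 3) -> (0.25, 0.75): scorer w=(0, ln3), annotations one-hot
    alpha = attention_weights(a, np.array([0.0, np.log(3.0)]), 0.0)
    assert np.allclose(alpha, [0.25, 0.75])
    # shift invariance via the scorer bias
    alpha_shift = attention_weights(a, np.array([0.0, np.log(3.0)]), 123.4)
    assert np.allclose(alpha, alpha_shift)


def test_attention_weights_stable_for_large_scores():
    ann = np.array([[1e4], [0.0]])
    alpha = attention_weights(ann, np.array([1.0]), 0.0)
    assert np.isfinite(alpha).all() and alpha.sum() == pytest.approx(1.0)


def test_context_vector_examples():
    a = np.array([[1.0, 0.0], [0.0, 1.0]])
    assert np.allclose(context_vector(a, np.array([1.0, 0.0])), [1.0, 0.0])  # one-hot
    assert np.allclose(context_vector(a, np.array([0.5, 0.5])), [0.5, 0.5])  # uniform mean
    assert np.allclose(context_vector(a, np.array([0.25, 0.75])), [0.25, 0.75])
    with pytest.raises(FormatError):
        context_vector(a, np.array([0.5, 0.25, 0.25]))


def test_equal_scores_give_uniform_profile_and_mean_context():
    spec = ModelSpec("attention", tx=6, input_dim=3, hidden=4, dropout=0.0,
                     include_mg_cluster=False)
    m = build_temporal_attention(spec, seed=0)
    m.params["ws"][:] = 0.0  # constant scores
    X = np.random.default_rng(0).normal(size=(2, 6, 3))
    _, cache = m.forward(X, np.empty((2, 0)))
    assert np.allclose(cache["alpha"], 1.0 / 6.0)
    assert np.allclose(cache["ctx"], cache["H2d"].mean(axis=1))


def test_attention_profiles_normalized_for_random_weights_and_inputs():
    rng = np.random.default_rng(5)
    for draw in range(100):
        spec = ModelSpec("attention", tx=int(rng.integers(2, 12)),
                         input_dim=3, hidden=5, include_mg_cluster=False)
        m = build_temporal_attention(spec, seed=draw)
        for k, v in m.params.items():
            m.params[k] = v + rng.normal(0, 0.5, v.shape)
        X = rng.normal(size=(4, spec.tx, 3))
        prof = m.attention_profiles(X, np.empty((4, 0)))
        assert np.all(prof >= 0)
        assert np.allclose(prof.sum(axis=1), 1.0, atol=1e-6)


def test_stacked_equals_attention_with_forced_one_hot_profile():
    spec_s = ModelSpec("stacked", tx=8, input_dim=4, hidden=6, context_dim=2, dropout=0.0)
    spec_a = ModelSpec("attention", tx=8, input_dim=4, hidden=6, context_dim=2, dropout=0.0)
    ms, ma = build_stacked_lstm(spec_s, seed=1), build_temporal_attention(spec_a, seed=2)
    for k in ms.params:  # share encoder and head weights
        ma.params[k] = ms.params[k].copy()
    rng = np.random.default_rng(3)
    X, side = rng.normal(size=(5, 8, 4)), rng.normal(size=(5, 2))
    ys, _ = ms.forward(X, side)
    one_hot = np.zeros(8)
    one_hot[-1] = 1.0
    ya, _ = ma.forward(X, side, force_alpha=one_hot)
    assert np.allclose(ys, ya, atol=1e-12)


def test_inference_is_deterministic_despite_dropout_spec():
    spec = ModelSpec("attention", tx=5, input_dim=3, hidden=4, dropout=0.5)
    m = build_temporal_attention(spec, seed=0)
    rng = np.random.default_rng(1)
    X, side = rng.normal(size=(7, 5, 3)), rng.normal(size=(7, 2))
    p1, p2 = m.predict(X, side), m.predict(X, side)
    assert np.array_equal(p1, p2)


def test_training_mode_requires_rng_and_dropout_changes_output():
    spec = ModelSpec("stacked", tx=4, input_dim=2, hidden=3, dropout=0.5,
                     include_mg_cluster=False)
    m = build_stacked_lstm(spec, seed=0)
    X = np.random.default_rng(0).normal(size=(3, 4, 2))
    with pytest.raises(ConfigurationError):
        m.forward(X, np.empty((3, 0)), train=True)
    y1, _ = m.forward(X, np.empty((3, 0)), train=True, drop_rng=np.random.default_rng(1))
    y0, _ = m.forward(X, np.empty((3, 0)))
    assert not np.allclose(y1, y0)


@pytest.mark.parametrize("variant", ["stacked", "attention"])
def test_backward_matches_finite_differences(variant):
    spec = ModelSpec(variant, tx=5, input_dim=3, hidden=3, context_dim=2, dropout=0.0)
    m = _build(spec, seed=1)
    rng = np.random.default_rng(0)
    X, side, y = rng.normal(size=(6, 5, 3)), rng.normal(size=(6, 2)), rng.normal(size=6)

    def loss():
        yh, _ = m.forward(X, side)
        return np.mean((yh - y) ** 2)

    yh, cache = m.forward(X, side)
    grads = m.backward(cache, 2.0 * (yh - y) / len(y))
    eps = 1e-5
    for k, v in m.params.items():
        ana = grads[k].reshape(v.shape)
        num = np.zeros_like(v)
        it = np.nditer(v, flags=["multi_index"])
        while not it.finished:
            idx = it.multi_index
            old = v[idx]
            v[idx] = old + eps
            lp = loss()
            v[idx] = old - eps
            lm = loss()
            v[idx] = old
            num[idx] = (lp - lm) / (2 * eps)
            it.iternext()
        assert np.allclose(num, ana, rtol=1e-4, atol=1e-8), k


def test_invalid_specs_rejected():
    with pytest.raises(ConfigurationError):
        ModelSpec("gru", tx=5, input_dim=3)
    with pytest.raises(ConfigurationError):
        ModelSpec("stacked", tx=5, input_dim=3, dropout=1.0)
    with pytest.raises(ConfigurationError):
        build_stacked_lstm(ModelSpec("attention", tx=5, input_dim=3))
    with pytest.raises(ConfigurationError):
        build_temporal_attention(ModelSpec("stacked", tx=5, input_dim=3))
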