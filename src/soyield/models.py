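"""Sequence regressors for many-to-one yield prediction.

Two architectures share a two-layer LSTM encoder over the Tx weather
time-steps (dropout after each layer):

* ``stacked``  -- the final annotation a^<Tx> is the sequence summary.
* ``attention`` -- a shared linear scorer (hidden -> 1, with bias) maps every
  annotation a^<t> to a score e^<t>; softmax over time gives the attention
  profile alpha, and the summary is the context c = sum_t alpha^<t> a^<t>.
  No decoder is used: the task is many-to-one.

The summary is reduced by a linear dense layer to ``context_dim`` units,
concatenated with the scaled maturity-group and cluster scalars (when
enabled), and mapped by a final linear unit to the scaled yield.

Everything -- forward pass, backpropagation through time, parameter
initialization -- is implemented in NumPy with float64 arithmetic, so runs
are bit-reproducible on CPU.  Parameter counts follow the single-bias LSTM
convention: 4h(d + h + 1) per layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, FormatError

__all__ = [
    "ModelSpec",
    "SequenceRegressor",
    "build_stacked_lstm",
    "build_temporal_attention",
    "attention_weights",
    "context_vector",
    "count_trainable_params",
    "expected_param_count",
]


@dataclass
class ModelSpec:
    """Architecture hyperparameters.

    Defaults mirror the tuned configuration: hidden size 128 in both LSTM
    layers, a 2-unit context reduction, dropout 0.2 after each LSTM layer.
    """

    variant: str
    tx: int
    input_dim: int
    hidden: int = 128
    context_dim: int = 2
    dropout: float = 0.2
    include_mg_cluster: bool = True

    def __post_init__(self) -> None:
        if self.variant not in ("stacked", "attention"):
            raise ConfigurationError(f"unknown variant {self.variant!r}")
        if self.hidden <= 0 or self.context_dim <= 0:
            raise ConfigurationError("hidden and context_dim must be positive")
        if not 0 <= self.dropout < 1:
            raise ConfigurationError("dropout must be in [0, 1)")
        if self.tx < 1 or self.input_dim < 1:
            raise ConfigurationError("tx and input_dim must be >= 1")

    @property
    def side_dim(self) -> int:
        return 2 if self.include_mg_cluster else 0


def _softmax(e: np.ndarray, axis: int = -1) -> np.ndarray:
    z = e - e.max(axis=axis, keepdims=True)
    w = np.exp(z)
    return w / w.sum(axis=axis, keepdims=True)


def attention_weights(annotations: np.ndarray, w: np.ndarray, b: float) -> np.ndarray:
    """Softmax-normalized profile over time from a shared linear scorer.

    ``annotations`` is (..., Tx, hidden); returns (..., Tx) summing to 1
    along time, numerically stabilized by max-subtraction.
    """
    e = annotations @ np.asarray(w).reshape(-1) + b
    return _softmax(e, axis=-1)


def context_vector(annotations: np.ndarray, profile: np.ndarray) -> np.ndarray:
    """Attention-weighted sum of annotations: c = sum_t alpha^<t> a^<t>."""
    annotations = np.asarray(annotations, dtype=float)
    profile = np.asarray(profile, dtype=float)
    if annotations.shape[:-1] != profile.shape:
        raise FormatError(
            f"profile shape {profile.shape} does not match annotations {annotations.shape}"
        )
    return (profile[..., None] * annotations).sum(axis=-2)


# ---------------------------------------------------------------------------
# parameter initialization
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / sum(shape))
    return rng.uniform(-limit, limit, shape)

def _orthogonal_gates(rng: np.random.Generator, h: int) -> np.ndarray:
    blocks = []
    for _ in range(4):
        q, r = np.linalg.qr(rng.normal(size=(h, h)))
        blocks.append(q * np.sign(np.diag(r)))
    return np.concatenate(blocks, axis=1)  # (h, 4h)


class SequenceRegressor:
    """A stacked-LSTM or temporal-attention yield regressor.

    Parameters live in ``self.params`` (dict of float64 arrays); ``forward``
    returns predictions plus a cache consumed by ``backward``, which yields
    exact gradients of the sum of upstream per-record gradients.
    """

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng([seed, 101])
        d, h, c = spec.input_dim, spec.hidden, spec.context_dim
        p: dict[str, np.ndarray] = {
            "W1": _glorot(rng, (d, 4 * h)),
            "U1": _orthogonal_gates(rng, h),
            "b1": np.zeros(4 * h),
            "W2": _glorot(rng, (h, 4 * h)),
            "U2": _orthogonal_gates(rng, h),
            "b2": np.zeros(4 * h),
            "Wc": _glorot(rng, (h, c)),
            "bc": np.zeros(c),
            "Wy": _glorot(rng, (c + spec.side_dim, 1)),
            "by": np.zeros(1),
        }
        if spec.variant == "attention":
            p["ws"] = _glorot(rng, (h, 1))[:, 0]
            p["bs"] = np.zeros(1)
        self.params = p

    # -- LSTM layer ---------------------------------------------------------

    @staticmethod
    def _lstm_forward(X, W, U, b):
        B, T, _ = X.shape
        h = U.shape[0]
        I = np.empty((B, T, h)); F = np.empty((B, T, h))
        G = np.empty((B, T, h)); O = np.empty((B, T, h))
        C = np.empty((B, T, h)); H = np.empty((B, T, h))
        h_prev = np.zeros((B, h)); c_prev = np.zeros((B, h))
        for t in range(T):
            z = X[:, t] @ W + h_prev @ U + b
            i = 1.0 / (1.0 + np.exp(-z[:, :h]))
            f = 1.0 / (1.0 + np.exp(-z[:, h : 2 * h]))
            g = np.tanh(z[:, 2 * h : 3 * h])
            o = 1.0 / (1.0 + np.exp(-z[:, 3 * h :]))
            c_prev = f * c_prev + i * g
            h_prev = o * np.tanh(c_prev)
            I[:, t], F[:, t], G[:, t], O[:, t] = i, f, g, o
            C[:, t], H[:, t] = c_prev, h_prev
        return H, (X, I, F, G, O, C, H)

    @staticmethod
    def _lstm_backward(dH_seq, cache, W, U):
        X, I, F, G, O, C, H = cache
        B, T, h = I.shape
        dW = np.zeros_like(W); dU = np.zeros_like(U); db = np.zeros(4 * h)
        dX = np.zeros_like(X)
        dh_next = np.zeros((B, h)); dc_next = np.zeros((B, h))
        for t in range(T - 1, -1, -1):
            i, f, g, o, c = I[:, t], F[:, t], G[:, t], O[:, t], C[:, t]
            tc = np.tanh(c)
            dh = dH_seq[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            c_prev = C[:, t - 1] if t > 0 else np.zeros((B, h))
            h_prev = H[:, t - 1] if t > 0 else np.zeros((B, h))
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
                axis=1,
            )
            dW += X[:, t].T @ dz
            dU += h_prev.T @ dz
            db += dz.sum(axis=0)
            dX[:, t] = dz @ W.T
            dh_next = dz @ U.T
            dc_next = dc * f
        return dX, dW, dU, db

    # -- full model ---------------------------------------------------------

    def forward(
        self,
        X: np.ndarray,
        side: np.ndarray,
        train: bool = False,
        drop_rng: np.random.Generator | None = None,
        force_alpha: np.ndarray | None = None,
    ):
        """Predict scaled yield for a batch.

        Dropout is active only when ``train`` is True (inverted dropout with
        masks drawn from ``drop_rng``).  ``force_alpha`` overrides the learned
        attention profile (diagnostic hook for architectural checks).
        Returns (predictions (B,), cache).
        """
        spec, p = self.spec, self.params
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[2] != spec.input_dim:
            raise FormatError(f"expected inputs (B, {spec.tx}, {spec.input_dim}), got {X.shape}")
        side = np.asarray(side, dtype=float).reshape(X.shape[0], -1)
        if side.shape[1] != spec.side_dim:
            raise FormatError(f"expected side dim {spec.side_dim}, got {side.shape[1]}")

        use_drop = train and spec.dropout > 0
        if use_drop and drop_rng is None:
            raise ConfigurationError("drop_rng required for training-mode forward")
        keep = 1.0 - spec.dropout

        H1, cache1 = self._lstm_forward(X, p["W1"], p["U1"], p["b1"])
        mask1 = (drop_rng.random(H1.shape) < keep) / keep if use_drop else None
        H1d = H1 * mask1 if use_drop else H1
        H2, cache2 = self._lstm_forward(H1d, p["W2"], p["U2"], p["b2"])
        mask2 = (drop_rng.random(H2.shape) < keep) / keep if use_drop else None
        H2d = H2 * mask2 if use_drop else H2

        alpha = None
        if spec.variant == "attention":
            if force_alpha is not None:
                alpha = np.broadcast_to(force_alpha, H2d.shape[:2]).astype(float)
            else:
                alpha = attention_weights(H2d, p["ws"], p["bs"][0])
            ctx = context_vector(H2d, alpha)
        else:
            if force_alpha is not None:
                raise ConfigurationError("force_alpha applies to the attention variant only")
            ctx = H2d[:, -1]

        q = ctx @ p["Wc"] + p["bc"]
        head_in = np.concatenate([q, side], axis=1) if spec.side_dim else q
        yhat = (head_in @ p["Wy"] + p["by"])[:, 0]
        cache = dict(
            cache1=cache1, cache2=cache2, mask1=mask1, mask2=mask2, H2d=H2d,
            alpha=alpha, ctx=ctx, q=q, head_in=head_in, forced=force_alpha is not None,
        )
        return yhat, cache

    def backward(self, cache: dict, dyhat: np.ndarray) -> dict[str, np.ndarray]:
        spec, p = self.spec, self.params
        c = spec.context_dim
        dy = np.asarray(dyhat, dtype=float)[:, None]
        grads: dict[str, np.ndarray] = {}
        grads["Wy"] = cache["head_in"].T @ dy
        grads["by"] = dy.sum(axis=0)
        dhead = dy @ p["Wy"].T
        dq = dhead[:, :c]
        grads["Wc"] = cache["ctx"].T @ dq
        grads["bc"] = dq.sum(axis=0)
        dctx = dq @ p["Wc"].T

        H2d = cache["H2d"]
        dH2d = np.zeros_like(H2d)
        if spec.variant == "attention":
            alpha = cache["alpha"]
            dH2d += alpha[..., None] * dctx[:, None, :]
            if cache["forced"]:
                grads["ws"] = np.zeros_like(p["ws"])
                grads["bs"] = np.zeros_like(p["bs"])
            else:
                dalpha = np.einsum("bh,bth->bt", dctx, H2d)
                de = alpha * (dalpha - (alpha * dalpha).sum(axis=1, keepdims=True))
                grads["ws"] = np.einsum("bt,bth->h", de, H2d)
                grads["bs"] = np.array([de.sum()])
                dH2d += de[..., None] * p["ws"][None, None, :]
        else:
            dH2d[:, -1] = dctx

        dH2 = dH2d * cache["mask2"] if cache["mask2"] is not None else dH2d
        dH1d, grads["W2"], grads["U2"], grads["b2"] = self._lstm_backward(
            dH2, cache["cache2"], p["W2"], p["U2"]
        )
        dH1 = dH1d * cache["mask1"] if cache["mask1"] is not None else dH1d
        _, grads["W1"], grads["U1"], grads["b1"] = self._lstm_backward(
            dH1, cache["cache1"], p["W1"], p["U1"]
        )
        return grads

    def predict(self, X: np.ndarray, side: np.ndarray, batch_size: int = 1024) -> np.ndarray:
        """Inference-mode predictions (dropout disabled, deterministic)."""
        out = []
        for s in range(0, len(X), batch_size):
            yhat, _ = self.forward(X[s : s + batch_size], side[s : s + batch_size], train=False)
            out.append(yhat)
        return np.concatenate(out)

    def attention_profiles(self, X: np.ndarray, side: np.ndarray, batch_size: int = 1024) -> np.ndarray:
        """Per-record attention profiles (attention variant only)."""
        if self.spec.variant != "attention":
            raise TypeError("attention profiles are defined for the attention variant only")
        out = []
        for s in range(0, len(X), batch_size):
            _, cache = self.forward(X[s : s + batch_size], side[s : s + batch_size], train=False)
            out.append(cache["alpha"])
        return np.concatenate(out)

    def n_params(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def parameter_table(self) -> list[tuple[str, int]]:
        return [(k, int(v.size)) for k, v in sorted(self.params.items())]


def build_stacked_lstm(spec: ModelSpec, seed: int = 0) -> SequenceRegressor:
    """Two stacked LSTM layers -> last annotation -> context dense -> head."""
    if spec.variant != "stacked":
        raise ConfigurationError("spec.variant must be 'stacked'")
    return SequenceRegressor(spec, seed=seed)


def build_temporal_attention(spec: ModelSpec, seed: int = 0) -> SequenceRegressor:
    """Same encoder with a softmax attention scorer over all annotations."""
    if spec.variant != "attention":
        raise ConfigurationError("spec.variant must be 'attention'")
    return SequenceRegressor(spec, seed=seed)


def count_trainable_params(model: SequenceRegressor) -> int:
    """Total scalar trainable parameters of a built model."""
    return model.n_params()


def expected_param_count(spec: ModelSpec) -> int:
    """Closed-form accounting: 4h(d+h+1) per LSTM layer, d*u+u per dense,
    h+1 for the attention scorer."""
    d, h, c = spec.input_dim, spec.hidden, spec.context_dim
    total = 4 * h * (d + h + 1) + 4 * h * (h + h + 1)
    total += h * c + c
    total += (c + spec.side_dim) * 1 + 1
    if spec.variant == "attention":
        total += h + 1
    return total
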