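"""Training/evaluation protocol, repeated runs, greedy variable selection
and classical baselines.

The protocol: records are randomly split 80/10/10 into train/validation/test;
features and target are min-max scaled to (-1, 1) on the training split;
models are trained with Adam on mean-squared error for a fixed number of
epochs (no early stopping); RMSE/MAE/R^2 are computed after inverting the
target scaling, i.e. in bu/acre.  Repeated runs re-train with fresh
initialization/training seeds on a fixed split and report mean +/- population
standard deviation per metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.linear_model import Lasso, LinearRegression
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score
from sklearn.svm import SVR

from .errors import (
    ConfigurationError,
    DivergenceError,
    EvaluationError,
    SoyieldError,
)
from .models import ModelSpec, SequenceRegressor, build_stacked_lstm
from .synthetic import WEATHER_VARS
from .weatherprep import MinMaxScaler, ModelInput, assemble_inputs

__all__ = [
    "TrainConfig",
    "Metrics",
    "EvalResult",
    "BaselineSpec",
    "GreedyTrace",
    "split_records",
    "train_model",
    "evaluate",
    "repeated_runs",
    "mae_percent",
    "greedy_search",
    "greedy_weather_search",
    "fit_baselines",
    "oracle_r2",
]


@dataclass
class TrainConfig:
    """Optimization settings (Adam on MSE, fixed epoch budget)."""

    learning_rate: float = 0.001
    epochs: int = 100
    batch_size: int = 512
    split: tuple[float, float, float] = (0.8, 0.1, 0.1)
    n_repeats: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ConfigurationError("split fractions must sum to 1")
        if self.epochs < 0 or self.batch_size <= 0:
            raise ConfigurationError("epochs must be >= 0 and batch_size > 0")
        if self.n_repeats < 1:
            raise ConfigurationError("n_repeats must be >= 1")


@dataclass
class Metrics:
    rmse: float
    mae: float
    r2: float


@dataclass
class EvalResult:
    """Per-repeat metrics with mean +/- population standard deviation."""

    repeats: list[Metrics]
    metadata: dict = field(default_factory=lambda: {"std_convention": "population"})

    def _arr(self, name: str) -> np.ndarray:
        return np.array([getattr(m, name) for m in self.repeats])

    def mean(self, name: str) -> float:
        return float(self._arr(name).mean())

    def std(self, name: str) -> float:
        return float(self._arr(name).std())  # ddof=0: population convention

    def summary(self) -> dict:
        out = {}
        for name in ("rmse", "mae", "r2"):
            out[name] = {"mean": self.mean(name), "std": self.std(name)}
        out["n_repeats"] = len(self.repeats)
        out.update(self.metadata)
        return out


def split_records(
    n: int, fractions: tuple[float, float, float] = (0.8, 0.1, 0.1), seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Record-level random partition into train/validation/test index sets."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError("fractions must sum to 1")
    if n < 3:
        raise ConfigurationError(f"need at least 3 records to split, got {n}")
    perm = np.random.default_rng([seed, 7]).permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    n_train = min(n_train, n - 2)
    n_val = max(1, min(n_val, n - n_train - 1))
    return perm[:n_train], perm[n_train : n_train + n_val], perm[n_train + n_val :]


class _Adam:
    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, g in grads.items():
            g = g.reshape(params[k].shape)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def train_model(
    model: SequenceRegressor,
    train: ModelInput,
    cfg: TrainConfig,
    val: ModelInput | None = None,
) -> dict[str, list[float]]:
    """Mini-batch Adam training on scaled-target MSE; model updated in place.

    Returns a history with per-epoch train loss (mean over batches) and, when
    a validation split is given, inference-mode validation loss.  A
    non-finite loss raises DivergenceError with the epoch index.
    """
    rng = np.random.default_rng([cfg.seed, 11])
    drop_rng = np.random.default_rng([cfg.seed, 12])
    opt = _Adam(model.params, cfg.learning_rate)
    n = len(train.y)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    for epoch in range(cfg.epochs):
        perm = rng.permutation(n)
        losses = []
        for s in range(0, n, cfg.batch_size):
            idx = perm[s : s + cfg.batch_size]
            yhat, cache = model.forward(train.X[idx], train.side[idx], train=True, drop_rng=drop_rng)
            err = yhat - train.y[idx]
            loss = float(np.mean(err**2))
            if not np.isfinite(loss):
                raise DivergenceError(epoch)
            grads = model.backward(cache, 2.0 * err / len(idx))
            opt.step(model.params, grads)
            losses.append(loss)
        history["train_loss"].append(float(np.mean(losses)))
        if val is not None and len(val.y):
            vp = model.predict(val.X, val.side)
            history["val_loss"].append(float(np.mean((vp - val.y) ** 2)))
    return history


def evaluate(
    model: SequenceRegressor, test: ModelInput, y_scaler: MinMaxScaler
) -> Metrics:
    """RMSE/MAE/R^2 on the original bu/acre scale (scaling inverted)."""
    if len(test.y) == 0:
        raise EvaluationError("empty test set")
    yhat = y_scaler.inverse(model.predict(test.X, test.side)[:, None])[:, 0]
    return prediction_metrics(test.y_raw, yhat)


def prediction_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> Metrics:
    if len(y_true) == 0:
        raise EvaluationError("empty evaluation set")
    return Metrics(
        rmse=float(np.sqrt(mean_squared_error(y_true, y_pred))),
        mae=float(mean_absolute_error(y_true, y_pred)),
        r2=float(r2_score(y_true, y_pred)),
    )


def repeated_runs(
    builder,
    train: ModelInput,
    test: ModelInput,
    y_scaler: MinMaxScaler,
    cfg: TrainConfig,
    val: ModelInput | None = None,
) -> EvalResult:
    """Train ``cfg.n_repeats`` independently seeded models on a fixed split.

    ``builder(seed)`` must return a fresh model; repeat r uses seed
    ``cfg.seed + r`` for both initialization and the training stream.
    """
    repeats = []
    for r in range(cfg.n_repeats):
        seed_r = cfg.seed + r
        model = builder(seed_r)
        try:
            train_model(model, train, replace(cfg, seed=seed_r), val=val)
        except SoyieldError as e:
            raise type(e)(f"repeat {r}: {e}") from e
        repeats.append(evaluate(model, test, y_scaler))
    return EvalResult(repeats)


def mae_percent(mae: float, reference: float) -> float:
    """MAE expressed as a percentage of a reference yield statistic."""
    if reference <= 0:
        raise ConfigurationError("reference must be positive")
    return 100.0 * mae / reference


# ---------------------------------------------------------------------------
# greedy forward variable selection
# ---------------------------------------------------------------------------

@dataclass
class GreedyStage:
    added: str
    score: float
    candidate_scores: dict[str, float]


@dataclass
class GreedyTrace:
    stages: list[GreedyStage]

    @property
    def ranking(self) -> list[str]:
        return [s.added for s in self.stages]

    def as_rows(self) -> list[dict]:
        rows = []
        for k, s in enumerate(self.stages):
            for var, score in s.candidate_scores.items():
                rows.append(
                    {"stage": k + 1, "candidate": var, "score": score,
                     "selected": var == s.added}
                )
        return rows


class GreedyStageError(SoyieldError):
    def __init__(self, stage: int, trace: GreedyTrace, cause: Exception):
        self.stage = stage
        self.trace = trace
        super().__init__(f"training failed at greedy stage {stage}: {cause}")


def greedy_search(candidates: list[str], evaluate_subset, n_stages: int | None = None) -> GreedyTrace:
    """Forward selection: at each stage train/evaluate one model per remaining
    candidate and add the argmin-criterion variable.

    ``evaluate_subset(tuple_of_variables) -> float`` supplies the criterion
    (lower is better).  Ties break by candidate order.  A training failure
    raises GreedyStageError carrying the trace built so far.
    """
    if not candidates:
        raise ConfigurationError("need at least one candidate variable")
    remaining = list(candidates)
    selected: list[str] = []
    stages: list[GreedyStage] = []
    total = len(candidates) if n_stages is None else min(n_stages, len(candidates))
    for stage in range(total):
        scores: dict[str, float] = {}
        for var in remaining:
            try:
                scores[var] = float(evaluate_subset(tuple(selected + [var])))
            except SoyieldError as e:
                raise GreedyStageError(stage + 1, GreedyTrace(stages), e) from e
        best = min(remaining, key=lambda v: (scores[v], remaining.index(v)))
        stages.append(GreedyStage(best, scores[best], scores))
        selected.append(best)
        remaining.remove(best)
    return GreedyTrace(stages)


def greedy_weather_search(
    records,
    weather,
    clusters,
    granularity: str,
    cfg: TrainConfig,
    spec_kwargs: dict | None = None,
    include_mg_cluster: bool = False,
    criterion: str = "val_rmse",
    variables: tuple[str, ...] = WEATHER_VARS,
    n_stages: int | None = None,
) -> GreedyTrace:
    """Greedy search over weather variables with the stacked-LSTM model.

    ``criterion`` is validation-set RMSE by default (no test leakage);
    ``"test_rmse"`` reproduces the protocol that ranks by test RMSE.
    """
    if criterion not in ("val_rmse", "test_rmse"):
        raise ConfigurationError(f"unknown criterion {criterion!r}")
    tr_idx, va_idx, te_idx = split_records(len(records), cfg.split, seed=cfg.seed)
    data, _, y_scaler = assemble_inputs(
        records, weather, clusters, granularity=granularity,
        include_mg_cluster=include_mg_cluster, train_idx=tr_idx,
    )
    train, val, test = data.subset(tr_idx), data.subset(va_idx), data.subset(te_idx)
    eval_on = val if criterion == "val_rmse" else test
    skw = dict(hidden=16, context_dim=2, dropout=0.2)
    skw.update(spec_kwargs or {})

    def evaluate_subset(subset: tuple[str, ...]) -> float:
        sub_train = train.select_features(list(subset))
        sub_eval = eval_on.select_features(list(subset))
        spec = ModelSpec(
            variant="stacked", tx=data.tx, input_dim=sub_train.input_dim,
            include_mg_cluster=include_mg_cluster, **skw,
        )
        model = build_stacked_lstm(spec, seed=cfg.seed)
        train_model(model, sub_train, cfg)
        return evaluate(model, sub_eval, y_scaler).rmse

    return greedy_search(list(variables), evaluate_subset, n_stages=n_stages)


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------

@dataclass
class BaselineSpec:
    """Classical baselines: SVR with RBF kernel and LASSO regression."""

    svr_epsilon: float = 0.1
    svr_c: float = 1.0
    lasso_alpha: float = 1e-6
    lasso_max_iter: int = 1000

    def __post_init__(self) -> None:
        if self.svr_epsilon <= 0 or self.svr_c <= 0 or self.lasso_alpha <= 0:
            raise ConfigurationError("epsilon, C and alpha must be positive")


def _flatten(data: ModelInput) -> np.ndarray:
    return np.concatenate([data.X.reshape(len(data.y), -1), data.side], axis=1)


def fit_baselines(
    train: ModelInput,
    test: ModelInput,
    y_scaler: MinMaxScaler,
    spec: BaselineSpec | None = None,
    which: tuple[str, ...] = ("svr", "lasso"),
) -> dict[str, dict]:
    """Fit SVR-RBF and/or LASSO on flattened sequences (Tx*dim + side).

    Both receive the same scaled features as the deep models; metrics are
    reported on the bu/acre scale with the hyperparameters echoed.
    """
    spec = spec or BaselineSpec()
    Xtr, Xte = _flatten(train), _flatten(test)
    if Xtr.shape[0] == 0 or Xte.shape[0] == 0:
        raise EvaluationError("empty train or test set for baselines")
    out: dict[str, dict] = {}
    for name in which:
        if name == "svr":
            est = SVR(kernel="rbf", epsilon=spec.svr_epsilon, C=spec.svr_c)
            params = {"epsilon": spec.svr_epsilon, "C": spec.svr_c, "kernel": "rbf"}
        elif name == "lasso":
            est = Lasso(alpha=spec.lasso_alpha, max_iter=spec.lasso_max_iter)
            params = {"alpha": spec.lasso_alpha, "max_iter": spec.lasso_max_iter}
        else:
            raise ConfigurationError(f"unknown baseline {name!r}")
        est.fit(Xtr, train.y)
        yhat = y_scaler.inverse(np.asarray(est.predict(Xte))[:, None])[:, 0]
        m = prediction_metrics(test.y_raw, yhat)
        out[name] = {"metrics": m, "params": params}
    return out


def oracle_r2(truth, train_idx: np.ndarray, test_idx: np.ndarray) -> float:
    """Generative-oracle R^2: linear regression of yield on the true effect
    components (cluster, MG adaptation, weather window), fit on the training
    rows and scored on the test rows."""
    feats = truth[["cluster_effect", "mg_term", "weather_term"]].to_numpy()
    y = truth["yield_bu_ac"].to_numpy()
    reg = LinearRegression().fit(feats[train_idx], y[train_idx])
    return float(r2_score(y[test_idx], reg.predict(feats[test_idx])))
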