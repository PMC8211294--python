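"""Weather downsampling, (-1, 1) min-max scaling and model-input assembly.

The 214-day growing season is downsampled to model time-steps over the first
210 days: weekly (Tx=30), biweekly (Tx=15) or monthly (Tx=7) windows; daily
keeps all 214 steps.  Downsampling preserves the sense of each variable --
mean of averages (ADNI, ARH, AvgSur), max of maxima (MDNI, MaxSur), min of
minima (MinSur); precipitation uses the window mean by default (window total
available behind a flag).  All features, including the maturity group, the
cluster ID and the target yield, are min-max scaled to (-1, 1) with
statistics fitted on the training split only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AssemblyError, ConfigurationError, FormatError
from .synthetic import N_DAYS, WEATHER_VARS, DailyWeatherSeries

__all__ = [
    "GRANULARITIES",
    "DownsampledSeries",
    "MinMaxScaler",
    "ModelInput",
    "downsample",
    "fit_scaler",
    "assemble_inputs",
]

#: granularity -> (window length in days, Tx)
GRANULARITIES: dict[str, tuple[int | None, int]] = {
    "daily": (None, 214),
    "weekly": (7, 30),
    "biweekly": (14, 15),
    "monthly": (30, 7),
}

_DOWNSAMPLE_DAYS = 210  # only the first 210 days enter non-daily windows

# aggregation rule per variable (AP handled separately for the total option)
_AGG = {
    "ADNI": np.mean,
    "ARH": np.mean,
    "AvgSur": np.mean,
    "AP": np.mean,
    "MDNI": np.max,
    "MaxSur": np.max,
    "MinSur": np.min,
}


@dataclass
class DownsampledSeries:
    """Tx x 7 matrix in canonical variable order."""

    tx: int
    values: np.ndarray


def downsample(
    daily: DailyWeatherSeries, granularity: str, ap_total: bool = False
) -> DownsampledSeries:
    """Aggregate a 214-day series into model time-steps.

    ``ap_total=True`` uses the window-total instead of window-mean for
    precipitation.  Daily granularity passes all 214 rows through unchanged.
    """
    if granularity not in GRANULARITIES:
        raise ConfigurationError(f"unknown granularity {granularity!r}")
    vals = np.asarray(daily.values, dtype=float)
    if vals.shape[0] != N_DAYS:
        raise FormatError(f"expected {N_DAYS} daily rows, got {vals.shape[0]}")
    window, tx = GRANULARITIES[granularity]
    if window is None:
        return DownsampledSeries(tx, vals.copy())

    out = np.empty((tx, len(WEATHER_VARS)))
    for j, var in enumerate(WEATHER_VARS):
        col = vals[:_DOWNSAMPLE_DAYS, j].reshape(tx, window)
        if var == "AP" and ap_total:
            out[:, j] = col.sum(axis=1)
        else:
            out[:, j] = _AGG[var](col, axis=1)
    return DownsampledSeries(tx, out)


@dataclass
class MinMaxScaler:
    """Per-feature linear map to (-1, 1): x -> 2 (x - min) / (max - min) - 1.

    Fitted on the training split only.  A constant feature maps to 0.
    """

    feature_names: list[str]
    mins: np.ndarray
    maxs: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        rng = self.maxs - self.mins
        safe = np.where(rng == 0, 1.0, rng)
        out = 2.0 * (X - self.mins) / safe - 1.0
        return np.where(rng == 0, 0.0, out)

    def inverse(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        rng = self.maxs - self.mins
        out = (X + 1.0) / 2.0 * rng + self.mins
        return np.where(rng == 0, self.mins, out)

    def column(self, name: str) -> "MinMaxScaler":
        j = self.feature_names.index(name)
        return MinMaxScaler([name], self.mins[j : j + 1], self.maxs[j : j + 1])

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "mins": [float(v) for v in self.mins],
            "maxs": [float(v) for v in self.maxs],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MinMaxScaler":
        return cls(list(d["feature_names"]), np.asarray(d["mins"]), np.asarray(d["maxs"]))


def fit_scaler(X: np.ndarray, feature_names: list[str]) -> MinMaxScaler:
    """Fit per-feature min/max on training inputs of shape (n, f) or (n, t, f)."""
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise AssemblyError("cannot fit scaler on an empty training set")
    flat = X.reshape(-1, X.shape[-1])
    return MinMaxScaler(list(feature_names), flat.min(axis=0), flat.max(axis=0))


@dataclass
class ModelInput:
    """Assembled tensors for one data split.

    ``X`` is (n, Tx, d) with d = 7 (weather only) or 9 (weather + MG +
    cluster repeated at every time-step); ``side`` is the (n, 2) MG/cluster
    head vector (empty when weather-only); ``y`` the scaled target and
    ``y_raw`` the original bu/acre yield.
    """

    X: np.ndarray
    side: np.ndarray
    y: np.ndarray
    y_raw: np.ndarray
    feature_names: list[str]
    record_index: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def tx(self) -> int:
        return self.X.shape[1]

    @property
    def input_dim(self) -> int:
        return self.X.shape[2]

    def subset(self, idx: np.ndarray) -> "ModelInput":
        return ModelInput(
            self.X[idx], self.side[idx], self.y[idx], self.y_raw[idx],
            list(self.feature_names), np.asarray(idx),
        )

    def select_features(self, names: list[str]) -> "ModelInput":
        """Restrict the per-step sequence to the named weather variables
        (MG/cluster columns, when present, are always retained)."""
        keep = [self.feature_names.index(n) for n in names]
        extra = [i for i, n in enumerate(self.feature_names) if n in ("MG", "cluster")]
        cols = keep + extra
        return ModelInput(
            self.X[:, :, cols], self.side, self.y, self.y_raw,
            [self.feature_names[i] for i in cols], self.record_index,
        )


def _raw_sequences(records, weather, granularity, ap_total):
    cache: dict[tuple[str, int], np.ndarray] = {}
    missing = []
    seqs = []
    for loc, yr in records[["location_id", "year"]].itertuples(index=False):
        key = (loc, int(yr))
        if key not in cache:
            if key not in weather:
                missing.append(key)
                continue
            cache[key] = downsample(weather[key], granularity, ap_total=ap_total).values
        seqs.append(cache[key])
    if missing:
        raise AssemblyError(f"records without weather: {sorted(set(missing))[:10]}")
    return np.stack(seqs)


def assemble_inputs(
    records: pd.DataFrame,
    weather: dict[tuple[str, int], DailyWeatherSeries],
    clusters: dict[str, int] | None,
    granularity: str = "weekly",
    include_mg_cluster: bool = True,
    train_idx: np.ndarray | None = None,
    ap_total: bool = False,
) -> tuple[ModelInput, MinMaxScaler, MinMaxScaler]:
    """Build scaled model inputs for all records.

    Per-step vectors hold the 7 downsampled weather features in canonical
    order; with ``include_mg_cluster`` the scaled MG and cluster ID are
    appended at every step (9-dim input) and also returned as the ``side``
    vector concatenated ahead of the prediction head.  Scaling statistics
    (including the target's) come from ``train_idx`` rows only (all rows if
    None).  Returns (inputs, feature_scaler, target_scaler).
    """
    if include_mg_cluster and clusters is None:
        raise AssemblyError("cluster assignment required when include_mg_cluster is set")
    seq = _raw_sequences(records, weather, granularity, ap_total)
    n, tx, _ = seq.shape
    names = list(WEATHER_VARS)

    if include_mg_cluster:
        missing = [g for g in records["genotype_id"].unique() if g not in clusters]
        if missing:
            raise AssemblyError(f"genotypes without cluster: {missing[:10]}")
        mg = records["mg"].to_numpy(dtype=float)
        cl = np.array([clusters[g] for g in records["genotype_id"]], dtype=float)
        extra = np.repeat(np.column_stack([mg, cl])[:, None, :], tx, axis=1)
        seq = np.concatenate([seq, extra], axis=2)
        names += ["MG", "cluster"]

    fit_rows = np.arange(n) if train_idx is None else np.asarray(train_idx)
    scaler = fit_scaler(seq[fit_rows], names)
    X = scaler.transform(seq)

    y_raw = records["yield_bu_ac"].to_numpy(dtype=float)
    y_scaler = fit_scaler(y_raw[fit_rows, None], ["yield_bu_ac"])
    y = y_scaler.transform(y_raw[:, None])[:, 0]

    side = X[:, 0, 7:9] if include_mg_cluster else np.empty((n, 0))
    return (
        ModelInput(X, side, y, y_raw, names, np.arange(n)),
        scaler,
        y_scaler,
    )
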