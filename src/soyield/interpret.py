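"""Attention-based interpretability.

Extracts per-record attention profiles from a trained temporal-attention
model, summarizes them stratified by actual-yield range and maturity group
(the growing-season "importance curve" readout), and quantifies how much
attention mass falls inside a given time-step window -- which, on synthetic
data with a planted effect window, becomes a localization diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EvaluationError
from .models import SequenceRegressor
from .weatherprep import ModelInput

__all__ = [
    "AttentionSummary",
    "LocalizationScore",
    "extract_profiles",
    "stratify_profiles",
    "localization_score",
    "plot_attention_summaries",
]


@dataclass
class AttentionSummary:
    """Mean attention curve and inter-quartile band for one stratum."""

    label: str
    mg: int | None
    yield_range: tuple[float, float]
    n_records: int
    mean_curve: np.ndarray
    q25: np.ndarray
    q75: np.ndarray


@dataclass
class LocalizationScore:
    """Attention mass inside a time-step window, with per-step densities so
    windows of different lengths compare fairly."""

    window: tuple[int, int]
    mass_in: float
    mass_in_per_step: float
    mass_out_per_step: float

    @property
    def density_ratio(self) -> float:
        return self.mass_in_per_step / self.mass_out_per_step


def extract_profiles(model: SequenceRegressor, data: ModelInput) -> np.ndarray:
    """One normalized attention profile per record (dropout disabled).

    Raises TypeError when the model is not the attention variant.
    """
    return model.attention_profiles(data.X, data.side)


def stratify_profiles(
    profiles: np.ndarray,
    records: pd.DataFrame,
    yield_breaks: list[float] | None = None,
    mg_values: tuple[int, ...] = (1, 7),
    min_n: int = 20,
) -> list[AttentionSummary]:
    """Bucket profiles by (MG, actual-yield range) and summarize each bucket.

    ``yield_breaks`` defaults to the within-MG yield quartiles.  Buckets with
    fewer than ``min_n`` records are omitted (returned summaries only).
    """
    profiles = np.asarray(profiles, dtype=float)
    if yield_breaks is not None and np.any(np.diff(yield_breaks) <= 0):
        raise ConfigurationError("yield_breaks must be strictly increasing")
    y = records["yield_bu_ac"].to_numpy(dtype=float)
    mg = records["mg"].to_numpy()
    out: list[AttentionSummary] = []
    for m in mg_values:
        sel = np.flatnonzero(mg == m)
        if sel.size == 0:
            continue
        breaks = (
            np.asarray(yield_breaks, dtype=float)
            if yield_breaks is not None
            else np.unique(np.quantile(y[sel], [0.0, 0.25, 0.5, 0.75, 1.0]))
        )
        for lo, hi in zip(breaks[:-1], breaks[1:]):
            in_range = sel[(y[sel] >= lo) & (y[sel] <= hi if hi == breaks[-1] else y[sel] < hi)]
            if in_range.size < max(min_n, 1):
                continue
            prof = profiles[in_range]
            out.append(
                AttentionSummary(
                    label=f"MG{m} yield [{lo:.1f}, {hi:.1f}]",
                    mg=int(m),
                    yield_range=(float(lo), float(hi)),
                    n_records=int(in_range.size),
                    mean_curve=prof.mean(axis=0),
                    q25=np.quantile(prof, 0.25, axis=0),
                    q75=np.quantile(prof, 0.75, axis=0),
                )
            )
    if not out:
        raise EvaluationError("no stratum met the minimum record count")
    return out


def localization_score(profiles: np.ndarray, window: tuple[int, int]) -> LocalizationScore:
    """Mean attention mass within a 1-based inclusive time-step window."""
    profiles = np.asarray(profiles, dtype=float)
    tx = profiles.shape[1]
    t0, t1 = window
    if not (1 <= t0 <= t1 <= tx):
        raise ConfigurationError(f"window must satisfy 1 <= t0 <= t1 <= {tx}, got {window}")
    inside = profiles[:, t0 - 1 : t1].sum(axis=1)
    mass_in = float(inside.mean())
    n_in = t1 - t0 + 1
    n_out = tx - n_in
    mass_out_per_step = (1.0 - mass_in) / n_out if n_out else float("nan")
    return LocalizationScore(
        window=(t0, t1),
        mass_in=mass_in,
        mass_in_per_step=mass_in / n_in,
        mass_out_per_step=mass_out_per_step,
    )


def profiles_to_frame(profiles: np.ndarray, record_ids=None) -> pd.DataFrame:
    n, tx = np.asarray(profiles).shape
    ids = np.arange(n) if record_ids is None else np.asarray(record_ids)
    return pd.DataFrame(
        {
            "record_id": np.repeat(ids, tx),
            "t": np.tile(np.arange(1, tx + 1), n),
            "alpha": np.asarray(profiles).ravel(),
        }
    )


def plot_attention_summaries(summaries: list[AttentionSummary], path: str) -> None:
    """One panel per MG: mean attention curves per yield stratum with IQR bands."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mgs = sorted({s.mg for s in summaries})
    fig, axes = plt.subplots(1, max(len(mgs), 1), figsize=(5 * max(len(mgs), 1), 3.5), squeeze=False)
    for ax, m in zip(axes[0], mgs):
        for s in [s for s in summaries if s.mg == m]:
            t = np.arange(1, len(s.mean_curve) + 1)
            ax.plot(t, s.mean_curve, label=f"[{s.yield_range[0]:.0f}, {s.yield_range[1]:.0f}] n={s.n_records}")
            ax.fill_between(t, s.q25, s.q75, alpha=0.15)
        ax.set_title(f"MG {m}")
        ax.set_xlabel("time-step")
        ax.set_ylabel("attention weight")
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
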