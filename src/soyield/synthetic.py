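"""Synthetic multi-environment soybean trial generator.

Emulates the schema of coordinated North-American variety trials: a pedigree
of breeding lines, daily growing-season weather per location-year, and plot
yield records (genotype x location x year, with maturity group).  The yield
surface is planted with known structure -- family (cluster) effects,
maturity-group x latitude adaptation, and a time-windowed weather effect --
so that every downstream stage (relatedness clustering, sequence regression,
greedy variable selection, attention interpretability) can be validated
against ground truth.

Yield model for a plot of genotype g at location l in year y:

    yield = base_yield
          + cluster_effect[family(g)]
          - mg_adapt_penalty * (MG_g - MG_opt(lat_l))^2
          + sum_v  effect_sizes[v] * z_v(l, y)
          + Normal(0, noise_sd)

where z_v(l, y) is the mean of weather variable v over ``effect_window``
(days, inclusive, 1-based), standardized across all generated location-years.
Every component is stored per record in the ``truth`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GenerationError

__all__ = [
    "WEATHER_VARS",
    "N_DAYS",
    "SyntheticConfig",
    "DailyWeatherSeries",
    "TrialBundle",
    "mg_optimal",
    "generate_pedigree",
    "generate_weather",
    "generate_yield",
    "generate_trial_bundle",
    "write_bundle",
    "read_weather_csv",
]

#: Canonical weather-variable order used throughout the package:
#: average direct normal irradiance (W m^-2), average precipitation (inches),
#: average relative humidity (%), maximum direct normal irradiance (W m^-2),
#: maximum / minimum / average surface temperature (degC).
WEATHER_VARS = ("ADNI", "AP", "ARH", "MDNI", "MaxSur", "MinSur", "AvgSur")

#: Growing-season length in days (April 1 through October 31).
N_DAYS = 214

_UNKNOWN = "NA"


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic trial generator.

    The defaults define a desk-scale study: ~200 lines in 5 pedigree
    families tested across 10 locations (latitudes 32-48 N) over 4 years,
    with a single signal-bearing weather variable (minimum surface
    temperature averaged over days 120-168, the pod-set/seed-fill phase)
    and family effects that make genotype-cluster input informative.
    """

    n_founders: int = 20
    n_generations: int = 3
    crosses_per_generation: int = 60
    n_clusters: int = 5
    n_locations: int = 10
    location_latitudes: tuple[float, ...] | None = None
    years: tuple[int, ...] = (2012, 2013, 2014, 2015)
    noise_sd: float = 2.1
    effect_window: tuple[int, int] = (120, 168)
    effect_sizes: dict[str, float] = field(default_factory=lambda: {"MinSur": 3.0})
    cluster_effect_sd: float = 4.0
    mg_adapt_penalty: float = 2.0
    base_yield: float = 45.0
    mg_window: float = 1.0
    planting_prob: float = 0.85
    # latitude anchors of the linear MG-adaptation map (MG 8 in the south,
    # MG 0 in the north); changing them changes the slope.
    lat_mg8: float = 30.0
    lat_mg0: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        d1, d2 = self.effect_window
        if not (1 <= d1 <= d2 <= N_DAYS):
            raise ConfigurationError(
                f"effect_window must satisfy 1 <= d1 <= d2 <= {N_DAYS}, got {self.effect_window}"
            )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.n_founders < 2:
            raise ConfigurationError("n_founders must be >= 2")
        if self.n_generations < 0 or self.crosses_per_generation < 0:
            raise ConfigurationError("generation/cross counts must be >= 0")
        if self.n_clusters < 1 or self.n_clusters > self.n_founders:
            raise ConfigurationError("need 1 <= n_clusters <= n_founders")
        if self.n_locations < 1:
            raise ConfigurationError("n_locations must be >= 1")
        if not 0 < self.planting_prob <= 1:
            raise ConfigurationError("planting_prob must be in (0, 1]")
        for v in self.effect_sizes:
            if v not in WEATHER_VARS:
                raise ConfigurationError(f"unknown weather variable {v!r}")
        lats = self.latitudes()
        if np.any(lats < 25) or np.any(lats > 55):
            raise ConfigurationError("latitudes must lie within [25, 55] degrees N")
        if len(lats) != self.n_locations:
            raise ConfigurationError("location_latitudes length must equal n_locations")

    def latitudes(self) -> np.ndarray:
        if self.location_latitudes is not None:
            return np.asarray(self.location_latitudes, dtype=float)
        if self.n_locations == 1:
            return np.array([40.0])
        return np.linspace(32.0, 48.0, self.n_locations)

    def location_ids(self) -> list[str]:
        return [f"LOC{i + 1:02d}" for i in range(self.n_locations)]


@dataclass
class DailyWeatherSeries:
    """One location-year of daily weather: a 214 x 7 matrix in WEATHER_VARS order."""

    location_id: str
    year: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_DAYS, len(WEATHER_VARS)):
            raise ConfigurationError(
                f"weather series must be {N_DAYS} x {len(WEATHER_VARS)}, got {self.values.shape}"
            )

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(WEATHER_VARS), index=np.arange(1, N_DAYS + 1))


@dataclass
class TrialBundle:
    """A complete synthetic study: records, pedigree, weather and ground truth."""

    records: pd.DataFrame  # genotype_id, location_id, year, mg, yield_bu_ac
    pedigree: pd.DataFrame  # id, parent1, parent2 ('NA' = unknown)
    weather: dict[tuple[str, int], DailyWeatherSeries]
    truth: pd.DataFrame  # per-record effect decomposition
    true_clusters: dict[str, int]
    config: SyntheticConfig

    def validate(self) -> None:
        for loc, yr in self.records[["location_id", "year"]].itertuples(index=False):
            if (loc, yr) not in self.weather:
                raise GenerationError(f"record references missing weather ({loc}, {yr})")
        ped_ids = set(self.pedigree["id"])
        missing = set(self.records["genotype_id"]) - ped_ids
        if missing:
            raise GenerationError(f"genotypes absent from pedigree: {sorted(missing)[:5]}")
        if not np.isfinite(self.records["yield_bu_ac"].to_numpy()).all():
            raise GenerationError("non-finite yields generated")


def mg_optimal(latitude: float | np.ndarray, cfg: SyntheticConfig) -> np.ndarray:
    """Optimal maturity group at a latitude: linear from MG 8 (south anchor)
    to MG 0 (north anchor), clipped to the MG 0-8 scale."""
    lat = np.asarray(latitude, dtype=float)
    frac = (cfg.lat_mg0 - lat) / (cfg.lat_mg0 - cfg.lat_mg8)
    return np.clip(8.0 * frac, 0.0, 8.0)


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def _pedigree_with_families(cfg: SyntheticConfig, rng: np.random.Generator):
    """Pedigree rows plus the family (true cluster) of every line.

    Founders are split round-robin into ``n_clusters`` families and crosses
    are made within a family, so families are mutually unrelated blocks whose
    structure is recoverable from the relationship matrix.
    """
    ids: list[str] = []
    p1s: list[str] = []
    p2s: list[str] = []
    family: dict[str, int] = {}
    members: list[list[str]] = [[] for _ in range(cfg.n_clusters)]

    for i in range(cfg.n_founders):
        gid = f"G{i + 1:04d}"
        fam = i % cfg.n_clusters
        ids.append(gid)
        p1s.append(_UNKNOWN)
        p2s.append(_UNKNOWN)
        family[gid] = fam
        members[fam].append(gid)

    nxt = cfg.n_founders + 1
    for _gen in range(cfg.n_generations):
        snapshot = [list(m) for m in members]  # parents come from earlier generations
        for k in range(cfg.crosses_per_generation):
            fam = int(rng.integers(cfg.n_clusters))
            pool = snapshot[fam]
            if len(pool) >= 2:
                pa, pb = rng.choice(len(pool), size=2, replace=False)
                p1, p2 = pool[pa], pool[pb]
            else:  # single-member family: self the line
                p1 = p2 = pool[0]
            gid = f"G{nxt:04d}"
            nxt += 1
            ids.append(gid)
            p1s.append(p1)
            p2s.append(p2)
            family[gid] = fam
            members[fam].append(gid)

    ped = pd.DataFrame({"id": ids, "parent1": p1s, "parent2": p2s})
    return ped, family


def generate_pedigree(cfg: SyntheticConfig) -> pd.DataFrame:
    """Generate an acyclic pedigree whose every line traces back to founders.

    Founders carry unknown (``'NA'``) parents; each non-founder has two
    parents drawn from earlier generations.  Deterministic given cfg.seed.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    ped, _ = _pedigree_with_families(cfg, rng)
    return ped


# ---------------------------------------------------------------------------
# weather
# ---------------------------------------------------------------------------

def _ar1(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    e = np.empty(n)
    innov = rng.normal(0.0, sd * np.sqrt(1.0 - rho**2), n)
    e[0] = rng.normal(0.0, sd)
    for t in range(1, n):
        e[t] = rho * e[t - 1] + innov[t]
    return e


def _one_series(lat: float, rng: np.random.Generator) -> np.ndarray:
    """One location-year, 214 x 7.  Seasonal sinusoid peaking mid-season,
    cooler and flatter at higher latitude, plus AR(1) day-to-day weather."""
    d = np.arange(1, N_DAYS + 1, dtype=float)
    season = np.sin(np.pi * d / N_DAYS)  # 0 at season edges, 1 mid-July

    mid = 12.0 - 0.35 * (lat - 40.0)  # baseline temperature level
    avg_sur = mid + 12.0 * season + _ar1(rng, N_DAYS, rho=0.7, sd=3.0)
    max_sur = avg_sur + 3.0 + rng.exponential(2.0, N_DAYS)
    min_sur = avg_sur - 3.5 - rng.exponential(2.0, N_DAYS)

    mdni = np.clip(550.0 + 280.0 * season + rng.normal(0.0, 60.0, N_DAYS), 50.0, None)
    adni = mdni * rng.uniform(0.35, 0.75, N_DAYS)

    ap = rng.binomial(1, 0.35, N_DAYS) * rng.exponential(0.15, N_DAYS)
    arh = np.clip(68.0 + _ar1(rng, N_DAYS, rho=0.6, sd=8.0), 0.0, 100.0)

    out = np.column_stack([adni, ap, arh, mdni, max_sur, min_sur, avg_sur])
    return out


def generate_weather(cfg: SyntheticConfig) -> dict[tuple[str, int], DailyWeatherSeries]:
    """Daily weather for every configured location-year.

    Guarantees MinSur <= AvgSur <= MaxSur and ADNI <= MDNI on every day,
    AP >= 0 and ARH within [0, 100].  Deterministic given cfg.seed.
    """
    lats = cfg.latitudes()
    out: dict[tuple[str, int], DailyWeatherSeries] = {}
    for li, loc in enumerate(cfg.location_ids()):
        for year in cfg.years:
            rng = np.random.default_rng([cfg.seed, 2, li, int(year)])
            out[(loc, year)] = DailyWeatherSeries(loc, int(year), _one_series(lats[li], rng))
    return out


# ---------------------------------------------------------------------------
# records and yield
# ---------------------------------------------------------------------------

def _generate_plan(cfg: SyntheticConfig, genotypes: list[str], rng: np.random.Generator) -> pd.DataFrame:
    """Assign each genotype an MG and plant it at locations within
    ``mg_window`` MG units of local adaptation, in each year w.p. planting_prob."""
    lats = cfg.latitudes()
    locs = cfg.location_ids()
    opt = mg_optimal(lats, cfg)
    rows = []
    for g in genotypes:
        mg = int(rng.integers(0, 9))
        eligible = [i for i in range(cfg.n_locations) if abs(mg - opt[i]) <= cfg.mg_window]
        for i in eligible:
            for year in cfg.years:
                if rng.random() < cfg.planting_prob:
                    rows.append((g, locs[i], int(year), mg))
    return pd.DataFrame(rows, columns=["genotype_id", "location_id", "year", "mg"])


def _window_z(cfg: SyntheticConfig, weather: dict) -> dict[str, dict[tuple[str, int], float]]:
    """Standardized effect-window anomalies per signal variable and location-year.

    The window mean is centered within location (removing the static
    latitude-driven level, which is already expressible through adaptation
    terms) before standardizing, so the planted weather effect is a genuinely
    temporal year-to-year signal rather than a geography proxy.
    """
    d1, d2 = cfg.effect_window
    z: dict[str, dict[tuple[str, int], float]] = {}
    keys = sorted(weather.keys(), key=lambda k: (k[0], k[1]))
    locs = np.array([k[0] for k in keys])
    for var in cfg.effect_sizes:
        j = WEATHER_VARS.index(var)
        means = np.array([weather[k].values[d1 - 1 : d2, j].mean() for k in keys])
        anom = means.copy()
        for loc in np.unique(locs):
            sel = locs == loc
            anom[sel] -= means[sel].mean()
        sd = anom.std()
        zz = np.zeros_like(anom) if sd == 0 else anom / sd
        z[var] = dict(zip(keys, zz))
    return z


def generate_yield(
    plan: pd.DataFrame,
    weather: dict[tuple[str, int], DailyWeatherSeries],
    families: dict[str, int],
    cfg: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the planted yield model to a planting plan.

    Returns (records, truth): records carry ``yield_bu_ac``; truth stores the
    exact additive decomposition (base, cluster, MG-adaptation, weather,
    noise) whose sum reproduces each yield.
    """
    for loc, yr in plan[["location_id", "year"]].drop_duplicates().itertuples(index=False):
        if (loc, yr) not in weather:
            raise GenerationError(f"no weather generated for ({loc}, {yr})")

    rng = np.random.default_rng([cfg.seed, 3])
    cluster_fx = rng.normal(0.0, cfg.cluster_effect_sd, cfg.n_clusters)
    z = _window_z(cfg, weather)
    lat_by_loc = dict(zip(cfg.location_ids(), cfg.latitudes()))

    n = len(plan)
    ce = np.array([cluster_fx[families[g]] for g in plan["genotype_id"]])
    opt = mg_optimal(np.array([lat_by_loc[l] for l in plan["location_id"]]), cfg)
    mg_term = -cfg.mg_adapt_penalty * (plan["mg"].to_numpy() - opt) ** 2
    weather_term = np.zeros(n)
    for var, beta in cfg.effect_sizes.items():
        weather_term += beta * np.array(
            [z[var][(l, y)] for l, y in plan[["location_id", "year"]].itertuples(index=False)]
        )
    noise = rng.normal(0.0, cfg.noise_sd, n) if cfg.noise_sd > 0 else np.zeros(n)

    y = cfg.base_yield + ce + mg_term + weather_term + noise
    records = plan.copy()
    records["yield_bu_ac"] = y
    truth = plan.copy()
    truth["base_yield"] = cfg.base_yield
    truth["cluster_effect"] = ce
    truth["mg_term"] = mg_term
    truth["weather_term"] = weather_term
    truth["noise"] = noise
    truth["yield_bu_ac"] = y
    return records, truth


def generate_trial_bundle(cfg: SyntheticConfig) -> TrialBundle:
    """Run the full generator: pedigree -> weather -> planting plan -> yields."""
    rng_ped = np.random.default_rng([cfg.seed, 1])
    pedigree, families = _pedigree_with_families(cfg, rng_ped)
    weather = generate_weather(cfg)
    rng_plan = np.random.default_rng([cfg.seed, 4])
    plan = _generate_plan(cfg, list(pedigree["id"]), rng_plan)
    records, truth = generate_yield(plan, weather, families, cfg)
    bundle = TrialBundle(records, pedigree, weather, truth, families, cfg)
    bundle.validate()
    return bundle


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def weather_to_long(weather: dict[tuple[str, int], DailyWeatherSeries]) -> pd.DataFrame:
    frames = []
    for (loc, yr) in sorted(weather.keys(), key=lambda k: (k[0], k[1])):
        s = weather[(loc, yr)]
        df = s.frame().reset_index(names="day").melt(
            id_vars="day", var_name="variable", value_name="value"
        )
        df.insert(0, "location_id", loc)
        df.insert(1, "year", yr)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def read_weather_csv(path: str | Path) -> dict[tuple[str, int], DailyWeatherSeries]:
    """Read long-format weather (location_id, year, day, variable, value)."""
    long = pd.read_csv(path)
    out = {}
    for (loc, yr), grp in long.groupby(["location_id", "year"], sort=True):
        wide = grp.pivot(index="day", columns="variable", values="value").sort_index()
        out[(loc, int(yr))] = DailyWeatherSeries(loc, int(yr), wide[list(WEATHER_VARS)].to_numpy())
    return out


def write_bundle(bundle: TrialBundle, outdir: str | Path) -> None:
    """Write records.csv, pedigree.csv, weather.csv and truth.csv (deterministic bytes)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fmt = "%.10g"
    bundle.records.to_csv(outdir / "records.csv", index=False, float_format=fmt)
    bundle.pedigree.to_csv(outdir / "pedigree.csv", index=False)
    weather_to_long(bundle.weather).to_csv(outdir / "weather.csv", index=False, float_format=fmt)
    bundle.truth.to_csv(outdir / "truth.csv", index=False, float_format=fmt)
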