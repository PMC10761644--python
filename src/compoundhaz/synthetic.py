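"""Synthetic surveillance inputs with known planted structure.

Every pipeline input — daily county temperature, weekly drought categories,
an ED-visit line list, county covariates and centroids — is generated here so
each downstream stage can be tested against planted ground truth without any
restricted data.

The study conditions emulated are a warm-season (May-September) county-level
surveillance system: a multi-year temperature climatology with seasonal cycle,
AR(1) day-to-day noise and Poisson-arriving hot spells; a first-order Markov
chain over the drought-category roster None, D0-D4; per-county-day Poisson
visit counts whose rate is multiplied by a planted relative risk on event
days inside a planted, spatially compact set of counties; and a covariate
table whose planted counties can carry configured mean shifts.

All generators are pure functions of (config, seed): sub-streams are derived
from the config seed with fixed stream codes, so regenerating any one input
is reproducible and independent of the others.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .covariates import PROPORTION_COLUMNS, assemble_covariates
from .exposure import HAZARD_COLUMNS, USDM_CATEGORIES

logger = logging.getLogger(__name__)

# sub-stream codes mixed with the config seed
_STREAM = {"counties": 1, "temperature": 2, "usdm": 3, "visits": 4,
           "covariates": 5, "partition": 6, "response": 7}


def _default_transition_matrix() -> np.ndarray:
    # persistent chain over None, D0, D1, D2, D3, D4; drought (>=D1)
    # occupies roughly a third of the stationary mass
    return np.array([
        [0.90, 0.08, 0.02, 0.00, 0.00, 0.00],
        [0.25, 0.55, 0.18, 0.02, 0.00, 0.00],
        [0.05, 0.25, 0.50, 0.18, 0.02, 0.00],
        [0.00, 0.08, 0.27, 0.50, 0.13, 0.02],
        [0.00, 0.02, 0.13, 0.30, 0.45, 0.10],
        [0.00, 0.00, 0.05, 0.25, 0.30, 0.40],
    ])


#: marginal (mean, sd) for each generated proportion/count covariate
DEFAULT_COVARIATE_MARGINALS = {
    "pct_age_65_plus": (0.17, 0.04),
    "pct_hs_grad_or_higher": (0.86, 0.05),
    "pct_no_vehicle": (0.07, 0.03),
    "pct_overcrowded": (0.03, 0.015),
    "pct_low_english": (0.04, 0.02),
    "pct_no_health_coverage": (0.11, 0.04),
    "pct_broadband": (0.78, 0.08),
    "homeowner_vacancy_rate": (0.02, 0.01),
    "rental_vacancy_rate": (0.07, 0.03),
    "pct_veterans": (0.08, 0.025),
    "pct_hispanic": (0.09, 0.05),
    "housing_units": (45000.0, 20000.0),
    "greenspace_per_person": (250.0, 80.0),  # m^2 per person
    "residential_segregation": (0.10, 0.15),  # ICE scale
}


class SizingError(ValueError):
    """Lattice too small for the requested number of counties."""


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic system.

    Temperature: daily mean ``mean_temp_c`` plus a seasonal cosine of
    amplitude ``seasonal_amplitude_c`` peaking at ``peak_doy`` (mid-July),
    AR(1) anomalies with lag-1 correlation ``ar1_rho`` and stationary
    standard deviation ``noise_sd_c`` (3 degC is typical of daily-mean
    anomalies), and hot spells arriving Poisson(``hot_spell_rate``) per
    county per warm season, each adding ``hot_spell_magnitude_c`` for
    ``3 + Poisson(2)`` days.

    Visits: per county-day Poisson counts at ``baseline_visit_rate`` per
    outcome, multiplied by ``planted_rr`` on days carrying the
    ``hazard_under_test`` flag inside ``planted_cluster_counties``.
    """

    n_counties: int = 20
    grid_shape: tuple[int, int] = (5, 4)
    spacing_km: float = 30.0
    climatology_years: tuple[int, int] = (2000, 2015)
    analysis_years: tuple[int, int] = (2016, 2019)
    warm_season: tuple[int, int] = (5, 9)
    outcomes: tuple[str, ...] = ("mood", "suicide")
    baseline_visit_rate: float = 0.5
    planted_cluster_counties: tuple[str, ...] | None = None
    planted_rr: float = 3.0
    hazard_under_test: str = "compound"
    mean_temp_c: float = 21.0
    seasonal_amplitude_c: float = 8.0
    peak_doy: int = 199
    ar1_rho: float = 0.7
    noise_sd_c: float = 3.0
    regional_weather_share: float = 0.9
    hot_spell_rate: float = 1.5
    hot_spell_magnitude_c: float = 6.0
    drought_transition_matrix: np.ndarray = field(
        default_factory=_default_transition_matrix)
    drought_spatial_coupling: float = 0.8
    heat_drought_coupling: float = 0.0
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"pct_overcrowded": 0.05,
                                 "greenspace_per_person": -120.0})
    covariate_marginals: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_MARGINALS))
    age_group_probs: tuple[float, ...] = (0.15, 0.60, 0.25)
    sex_probs: tuple[float, ...] = (0.60, 0.40)
    seed: int = 0

    def __post_init__(self):
        self.drought_transition_matrix = np.asarray(
            self.drought_transition_matrix, dtype=float)
        self.validate()

    def validate(self) -> None:
        rows, cols = self.grid_shape
        if rows * cols < self.n_counties:
            raise SizingError(
                f"grid {rows}x{cols} too small for {self.n_counties} counties")
        if self.planted_rr <= 0:
            raise ValueError("planted_rr must be positive")
        if self.baseline_visit_rate < 0:
            raise ValueError("baseline_visit_rate must be non-negative")
        m = self.drought_transition_matrix
        if m.shape != (6, 6) or (m < 0).any() or \
                not np.allclose(m.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("drought transition matrix must be 6x6"
                             " row-stochastic (rows sum to 1 within 1e-12)")
        lo, hi = self.warm_season
        if not (1 <= lo <= hi <= 12):
            raise ValueError("warm season must lie within the calendar year")
        if not (0.0 <= self.regional_weather_share <= 1.0
                and 0.0 <= self.drought_spatial_coupling <= 1.0):
            raise ValueError("spatial share/coupling must lie in [0, 1]")
        if self.hazard_under_test not in HAZARD_COLUMNS:
            raise ValueError(
                f"unknown hazard_under_test {self.hazard_under_test!r}")
        if self.climatology_years[1] - self.climatology_years[0] + 1 < 2:
            raise ValueError("need at least 2 climatology years")
        ids = set(self.county_ids())
        planted = set(self.resolved_planted())
        if not planted <= ids:
            raise ValueError(
                f"planted counties outside the lattice: {sorted(planted - ids)}")
        unknown = set(self.covariate_effects) - set(self.covariate_marginals)
        if unknown:
            raise ValueError(
                f"covariate_effects on unknown covariates: {sorted(unknown)}")

    def county_ids(self) -> list[str]:
        return [f"C{k:03d}" for k in range(self.n_counties)]

    def resolved_planted(self) -> tuple[str, ...]:
        """Planted set; default is a compact 2x2 lattice block at the origin."""
        if self.planted_cluster_counties is not None:
            return tuple(self.planted_cluster_counties)
        _, cols = self.grid_shape
        block = [0, 1, cols, cols + 1]
        ids = self.county_ids()
        return tuple(ids[k] for k in block if k < self.n_counties)

    def rng(self, stream: str, extra: int = 0) -> np.random.Generator:
        return np.random.default_rng(
            [int(self.seed), _STREAM[stream], int(extra)])


def make_counties(config: SyntheticConfig) -> pd.DataFrame:
    """Counties on a regular lattice: county_id, x_km, y_km, population."""
    rows, cols = config.grid_shape
    rng = config.rng("counties")
    recs = []
    for k, cid in enumerate(config.county_ids()):
        r, c = divmod(k, cols)
        recs.append((cid, c * config.spacing_km, r * config.spacing_km,
                     int(rng.integers(20_000, 200_000))))
    return pd.DataFrame(recs, columns=["county_id", "x_km", "y_km",
                                       "population"])


def _season_days(year: int, warm_season: tuple[int, int]) -> pd.DatetimeIndex:
    lo, hi = warm_season
    start = pd.Timestamp(year=year, month=lo, day=1)
    end = (pd.Timestamp(year=year, month=hi, day=1)
           + pd.offsets.MonthEnd(0))
    return pd.date_range(start, end, freq="D")


def _ar1_series(rng: np.random.Generator, n: int, rho: float) -> np.ndarray:
    """Stationary unit-variance AR(1) path."""
    if rho == 0:
        return rng.normal(0.0, 1.0, n)
    innov = rng.normal(0.0, np.sqrt(1 - rho ** 2), n)
    out = np.empty(n)
    out[0] = rng.normal(0.0, 1.0)
    for i in range(1, n):
        out[i] = rho * out[i - 1] + innov[i]
    return out


def simulate_temperature(counties: pd.DataFrame,
                         config: SyntheticConfig) -> pd.DataFrame:
    """Daily mean temperature per county over climatology + analysis years.

    seasonal cosine + AR(1) anomalies + planted hot-spell bumps.  Heat is a
    synoptic-scale phenomenon, so the anomaly mixes a region-wide AR(1)
    series (variance share ``regional_weather_share``, default 0.9 — about
    the inter-county daily-anomaly correlation across a single state) with a
    county-specific AR(1) remainder, and hot spells are region-wide events
    hitting every county on the same days.  Spells occur at the same rate in
    climatology and analysis years, so the percentile thresholds reflect
    them.
    """
    y0 = config.climatology_years[0]
    y1 = config.analysis_years[1]
    dates = pd.date_range(f"{y0}-01-01", f"{y1}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy()
    seasonal = (config.mean_temp_c + config.seasonal_amplitude_c
                * np.cos(2 * np.pi * (doy - config.peak_doy) / 365.0))
    n = len(dates)

    rng_region = config.rng("temperature", 1_000_000)
    share = config.regional_weather_share
    common = _ar1_series(rng_region, n, config.ar1_rho) if share > 0 \
        else np.zeros(n)
    bump = np.zeros(n)
    if config.hot_spell_rate > 0:
        for year in range(y0, y1 + 1):
            season = _season_days(year, config.warm_season)
            offset = (season[0] - dates[0]).days
            for _ in range(rng_region.poisson(config.hot_spell_rate)):
                dur = 3 + int(rng_region.poisson(2))
                start = offset + int(rng_region.integers(0, len(season)))
                bump[start:start + dur] += config.hot_spell_magnitude_c

    frames = []
    for k, cid in enumerate(counties["county_id"]):
        rng = config.rng("temperature", k)
        own = _ar1_series(rng, n, config.ar1_rho) if share < 1 \
            else np.zeros(n)
        noise = config.noise_sd_c * (np.sqrt(share) * common
                                     + np.sqrt(1 - share) * own)
        frames.append(pd.DataFrame({
            "county_id": cid, "date": dates,
            "tmean_c": seasonal + noise + bump}))
    return pd.concat(frames, ignore_index=True)


def stationary_distribution(matrix: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    w, v = np.linalg.eig(matrix.T)
    k = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, k])
    return pi / pi.sum()


def simulate_usdm(counties: pd.DataFrame, config: SyntheticConfig,
                  hot_spell_weeks: set | None = None) -> pd.DataFrame:
    """Weekly drought categories per county (first-order Markov chain).

    Weeks are Tuesday-anchored (USDM release convention) and cover the
    analysis years; a 26-week burn-in precedes the first reported week.
    Droughts are regional, so each week a county's transition draws from a
    region-wide uniform with probability ``drought_spatial_coupling`` (and
    its own uniform otherwise); every county's marginal law is still exactly
    the configured chain.  With ``heat_drought_coupling`` > 0 and
    ``hot_spell_weeks`` given (set of (county_id, week_start)), transitions
    toward wetter categories are down-weighted by that factor in the week
    following a hot spell.
    """
    m = config.drought_transition_matrix
    cum = np.cumsum(m, axis=1)
    y0, y1 = config.analysis_years
    first = pd.Timestamp(f"{y0}-01-01")
    first_tue = first - pd.Timedelta(days=(first.dayofweek - 1) % 7)
    weeks = pd.date_range(first_tue, f"{y1}-12-31", freq="7D")
    burn = 26
    n_steps = burn + len(weeks)
    rng_region = config.rng("usdm", 1_000_000)
    shared_u = rng_region.random(n_steps)
    frames = []
    for k, cid in enumerate(counties["county_id"]):
        rng = config.rng("usdm", k)
        own_u = rng.random(n_steps)
        use_shared = rng.random(n_steps) < config.drought_spatial_coupling
        state = 0  # start from "None", then burn in
        cats = []
        for step in range(n_steps):
            u = shared_u[step] if use_shared[step] else own_u[step]
            if (config.heat_drought_coupling > 0 and hot_spell_weeks
                    and step >= burn):
                week = weeks[step - burn]
                prev = week - pd.Timedelta(days=7)
                if (cid, prev) in hot_spell_weeks:
                    row = m[state].copy()
                    wetter = np.arange(6) < state
                    row[wetter] *= (1 - config.heat_drought_coupling)
                    row /= row.sum()
                    state = int(np.searchsorted(np.cumsum(row), u,
                                                side="right"))
                else:
                    state = int(np.searchsorted(cum[state], u, side="right"))
            else:
                state = int(np.searchsorted(cum[state], u, side="right"))
            state = min(state, 5)
            if step >= burn:
                cats.append(USDM_CATEGORIES[state])
        frames.append(pd.DataFrame({"county_id": cid, "week_start": weeks,
                                    "category": cats}))
    return pd.concat(frames, ignore_index=True)


def simulate_visits(counties: pd.DataFrame, calendar: pd.DataFrame,
                    config: SyntheticConfig,
                    replicate: int = 0) -> pd.DataFrame:
    """ED-visit line list: date, county_id, outcome, age_group, sex.

    Per county-day and outcome the visit count is Poisson(baseline * RR)
    where RR = ``planted_rr`` iff the day carries the hazard-under-test flag
    and the county is planted, else 1.  Only warm-season days present in the
    calendar generate visits.  ``replicate`` shifts the random stream so
    repeated visit draws over a fixed calendar are independent.
    """
    if config.baseline_visit_rate < 0:
        raise ValueError("baseline_visit_rate must be non-negative")
    col = HAZARD_COLUMNS[config.hazard_under_test]
    months = pd.DatetimeIndex(calendar["date"]).month
    lo, hi = config.warm_season
    cal = calendar[(months >= lo) & (months <= hi)]
    planted = set(config.resolved_planted())
    age_labels = ("0-12", "13-18", "19-24")
    rows = {"date": [], "county_id": [], "outcome": [], "age_group": [],
            "sex": []}
    for k, cid in enumerate(counties["county_id"]):
        rng = config.rng("visits", k * 1_000_003 + replicate)
        sub = cal[cal["county_id"] == cid]
        dates = pd.DatetimeIndex(sub["date"])
        event = sub[col].to_numpy(dtype=bool)
        lam = np.where(event & (cid in planted),
                       config.baseline_visit_rate * config.planted_rr,
                       config.baseline_visit_rate)
        for outcome in config.outcomes:
            counts = rng.poisson(lam)
            total = int(counts.sum())
            if total == 0:
                continue
            rows["date"].append(np.repeat(dates.to_numpy(), counts))
            rows["county_id"].append(np.full(total, cid, dtype=object))
            rows["outcome"].append(np.full(total, outcome, dtype=object))
            rows["age_group"].append(rng.choice(
                age_labels, size=total, p=config.age_group_probs))
            rows["sex"].append(rng.choice(
                ("F", "M"), size=total, p=config.sex_probs))
    if not rows["date"]:
        return pd.DataFrame(columns=["date", "county_id", "outcome",
                                     "age_group", "sex"])
    out = pd.DataFrame({k: np.concatenate(v) for k, v in rows.items()})
    out["date"] = pd.DatetimeIndex(out["date"])
    return out.sort_values(["date", "county_id", "outcome"],
                           kind="stable").reset_index(drop=True)


@dataclass
class SimulatedCovariates:
    props: pd.DataFrame
    greenspace: pd.DataFrame
    ice_counts: pd.DataFrame
    table: pd.DataFrame  #: assembled covariate table


def simulate_covariates(counties: pd.DataFrame,
                        config: SyntheticConfig) -> SimulatedCovariates:
    """County covariates with configured mean shifts in planted counties.

    Proportions draw from truncated normal marginals (clipped to [0, 1] with
    a warning when an effect pushes the mean outside); greenspace per person
    and housing units are non-negative; ICE inputs are generated as
    advantaged/deprived/total counts consistent with the target segregation
    marginal, so the assembled ICE reproduces the planted shift.
    """
    rng = config.rng("covariates")
    planted = set(config.resolved_planted())
    ids = counties["county_id"].to_list()
    pop = counties.set_index("county_id")["population"]
    is_planted = np.array([cid in planted for cid in ids])

    def draw(name, lo=None, hi=None):
        mean, sd = config.covariate_marginals[name]
        shift = config.covariate_effects.get(name, 0.0)
        mu = np.where(is_planted, mean + shift, mean)
        vals = rng.normal(mu, sd)
        if lo is not None or hi is not None:
            clipped = vals.copy()
            if lo is not None:
                clipped = np.maximum(clipped, lo)
            if hi is not None:
                clipped = np.minimum(clipped, hi)
            n_clip = int((clipped != vals).sum())
            if n_clip and shift != 0.0:
                logger.warning("covariate %s: %d values clipped to bounds"
                               " after planted shift", name, n_clip)
            vals = clipped
        return vals

    props = pd.DataFrame({"county_id": ids})
    for colname in PROPORTION_COLUMNS:
        props[colname] = draw(colname, 0.0, 1.0)
    props["housing_units"] = np.round(draw("housing_units", 1000.0)).astype(int)

    green_pp = draw("greenspace_per_person", 1.0)  # m^2 / person
    greenspace = pd.DataFrame({
        "county_id": ids,
        "green_area_km2": green_pp * pop.loc[ids].to_numpy() / 1e6,
        "population": pop.loc[ids].to_numpy()})

    # ICE counts consistent with the target segregation marginal:
    # advantaged/deprived shares move half an effect each way
    ice_rows = []
    seg = draw("residential_segregation", -1.0, 1.0)
    for variant in ("racial", "economic", "racialized_economic"):
        jitter = rng.normal(0.0, 0.03, len(ids))
        ice = np.clip(seg + jitter, -0.95, 0.95)
        f_adv = np.clip(0.40 + ice / 2.0, 0.0, 0.95)
        f_dep = np.clip(f_adv - ice, 0.0, 0.95)
        total = pop.loc[ids].to_numpy()
        ice_rows.append(pd.DataFrame({
            "county_id": ids, "variant": variant,
            "advantaged": np.round(f_adv * total).astype(int),
            "deprived": np.round(f_dep * total).astype(int),
            "total": total}))
    ice_counts = pd.concat(ice_rows, ignore_index=True)
    table = assemble_covariates(props, greenspace, ice_counts)
    return SimulatedCovariates(props=props, greenspace=greenspace,
                               ice_counts=ice_counts, table=table)


def simulate_mars_response(covariate_table: pd.DataFrame,
                           effects: dict[str, float],
                           baseline_mean: float = 8.0,
                           seed: int = 0) -> np.ndarray:
    """Poisson county counts driven by named covariates.

    log-mean = log(baseline_mean) + sum_v effects[v] * z_v with z_v the
    standardized covariate column; covariates not named contribute nothing
    (pure noise predictors for recovery studies).
    """
    rng = np.random.default_rng([int(seed), _STREAM["response"]])
    eta = np.full(len(covariate_table), np.log(baseline_mean))
    for name, coef in effects.items():
        x = covariate_table[name].to_numpy(dtype=float)
        sd = x.std()
        if sd == 0:
            raise ValueError(f"covariate {name} is constant")
        eta = eta + coef * (x - x.mean()) / sd
    return rng.poisson(np.exp(eta))


# ---------------------------------------------------------------------------
# writers (all dates ISO-8601)

def write_counties_csv(counties: pd.DataFrame, path) -> None:
    counties.to_csv(path, index=False)


def write_temperature_csv(temps: pd.DataFrame, path) -> None:
    out = temps.copy()
    out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def write_usdm_csv(usdm: pd.DataFrame, path) -> None:
    out = usdm.copy()
    out["week_start"] = pd.DatetimeIndex(out["week_start"]).strftime(
        "%Y-%m-%d")
    out.to_csv(path, index=False)


def write_visits_csv(visits: pd.DataFrame, path) -> None:
    out = visits.copy()
    out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def write_centroids_geojson(counties: pd.DataFrame, path) -> None:
    """Point GeoJSON of county centroids (planar km coordinates)."""
    features = [{
        "type": "Feature",
        "geometry": {"type": "Point",
                     "coordinates": [float(r.x_km), float(r.y_km)]},
        "properties": {"county_id": r.county_id,
                       "population": int(r.population)},
    } for r in counties.itertuples()]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh,
                  indent=1)


def read_temperature_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["date"])


def read_usdm_csv(path) -> pd.DataFrame:
    # keep_default_na: the category "None" is a real USDM level, not missing
    return pd.read_csv(path, parse_dates=["week_start"],
                       keep_default_na=False)


def read_visits_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["date"])


def config_to_dict(config: SyntheticConfig) -> dict:
    d = dataclasses.asdict(config)
    d["drought_transition_matrix"] = \
        config.drought_transition_matrix.tolist()
    return d


def write_config_yaml(config: SyntheticConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(json.loads(json.dumps(config_to_dict(config))), fh)


def read_config_yaml(path) -> SyntheticConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    for key in ("grid_shape", "climatology_years", "analysis_years",
                "warm_season", "outcomes", "age_group_probs", "sex_probs"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    if d.get("planted_cluster_counties") is not None:
        d["planted_cluster_counties"] = tuple(d["planted_cluster_counties"])
    if "covariate_marginals" in d:
        d["covariate_marginals"] = {k: tuple(v) for k, v
                                    in d["covariate_marginals"].items()}
    return SyntheticConfig(**d)
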