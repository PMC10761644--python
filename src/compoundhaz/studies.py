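"""Replicated simulation studies validating the pipeline end to end.

These are the package's built-in operating-characteristic checks, run over
planted synthetic data:

* :func:`null_calibration` — with no planted risk (RR = 1) the scan's
  primary-cluster Monte Carlo p-value should be uniform-to-conservative,
  so P(p <= 0.05) should not exceed the nominal level by more than Monte
  Carlo noise.
* :func:`planted_recovery` — with a planted relative risk of 3 on event
  days in a compact county block, the primary cluster should recover the
  planted set (Jaccard overlap of memberships).
* :func:`mars_recovery` — with two covariates driving Poisson county counts
  and the rest pure noise, the MARS importance ranking should place the two
  drivers on top, the first at exactly 100.
* :func:`t90_exceedance_percent` — by construction of the percentile
  climatology, about 10% of climatology days exceed t90 in every county.

The exposure calendar is generated once per study and held fixed across
replicates (the analysis conditions on exposure); visit noise and the scan's
Monte Carlo stream are re-drawn each replicate.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from . import exposure, mars, scan, synthetic
from .covariates import COVARIATE_ROSTER
from .pipeline import build_exposure

logger = logging.getLogger(__name__)

#: response-side effects (per standardized covariate) for the MARS study
DEFAULT_MARS_EFFECTS = {"pct_overcrowded": 1.0,
                        "greenspace_per_person": -1.0}


def _study_system(config: synthetic.SyntheticConfig):
    """Counties, calendar and centroids for one fixed exposure realisation."""
    counties = synthetic.make_counties(config)
    temps = synthetic.simulate_temperature(counties, config)
    usdm = synthetic.simulate_usdm(counties, config)
    _, _, _, calendar = build_exposure(temps, usdm, config)
    return counties, temps, calendar


def _warm_season_event_days(calendar: pd.DataFrame, hazard: str,
                            season: tuple[int, int]) -> int:
    months = pd.DatetimeIndex(calendar["date"]).month
    warm = calendar[(months >= season[0]) & (months <= season[1])]
    return int(warm[exposure.HAZARD_COLUMNS[hazard]].sum())


def null_calibration(n_replicates: int = 200, seed: int = 0,
                     target_cases: float = 60.0, hazard: str = "heatwave",
                     n_sim: int = 999, n_counties: int = 20) -> dict:
    """Primary-cluster p-values over replicates with no planted risk.

    The scan's null hypothesis is spatially *uniform* case probability, so
    the null study makes the weather fully regional
    (``regional_weather_share=1``): every county then shares one event
    calendar, a visit's case status is independent of its county, and the
    permutation p-value is exactly valid.  (Under the generator default of
    0.9 the residual county-level differences in event-day frequency are a
    genuine, if mild, departure from that null which the scan legitimately
    detects.)  The baseline visit rate is set so the expected case total is
    ``target_cases`` given the (fixed) exposure calendar's event
    county-days.  Returns the fraction of replicates with p <= 0.05 plus
    the p-values.
    """
    cfg = synthetic.SyntheticConfig(
        n_counties=n_counties, planted_rr=1.0, hazard_under_test=hazard,
        outcomes=("mood",), regional_weather_share=1.0, seed=seed)
    counties, _, calendar = _study_system(cfg)
    event_days = _warm_season_event_days(calendar, hazard, cfg.warm_season)
    if event_days == 0:
        raise RuntimeError(f"no {hazard} event days in the study calendar")
    cfg = dataclasses.replace(cfg,
                              baseline_visit_rate=target_cases / event_days)
    centroids = counties[["county_id", "x_km", "y_km"]]
    p_values = []
    for rep in range(n_replicates):
        visits = synthetic.simulate_visits(counties, calendar, cfg,
                                           replicate=rep + 1)
        counts = scan.aggregate_case_control(visits, calendar, hazard,
                                             "mood", season=cfg.warm_season)
        if counts["cases"].sum() < 1:
            p_values.append(1.0)
            continue
        windows = scan.generate_windows(centroids, counts)
        clusters = scan.run_scan(counts, windows, n_sim=n_sim,
                                 seed=(seed * 1_000_003 + rep) % 2**31,
                                 alpha=None)
        p_values.append(clusters[0].p_value if clusters else 1.0)
    p = np.asarray(p_values)
    return {"fraction_significant": float((p <= 0.05).mean()),
            "n_replicates": n_replicates,
            "mean_cases": target_cases, "p_values": p}


def jaccard(a, b) -> float:
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def planted_recovery(n_replicates: int = 50, seed: int = 0,
                     planted_rr: float = 3.0, baseline: float = 0.5,
                     hazard: str = "heatwave", n_sim: int = 999,
                     jaccard_threshold: float = 0.6,
                     n_counties: int = 20) -> dict:
    """Jaccard overlap of the pruned primary cluster with the planted set."""
    cfg = synthetic.SyntheticConfig(
        n_counties=n_counties, planted_rr=planted_rr,
        baseline_visit_rate=baseline, hazard_under_test=hazard,
        outcomes=("mood",), seed=seed)
    counties, _, calendar = _study_system(cfg)
    event_days = _warm_season_event_days(calendar, hazard, cfg.warm_season)
    if event_days < 100:
        logger.warning("only %d event county-days; recovery study is"
                       " under-powered", event_days)
    planted = set(cfg.resolved_planted())
    centroids = counties[["county_id", "x_km", "y_km"]]
    overlaps = []
    for rep in range(n_replicates):
        visits = synthetic.simulate_visits(counties, calendar, cfg,
                                           replicate=rep + 1)
        counts = scan.aggregate_case_control(visits, calendar, hazard,
                                             "mood", season=cfg.warm_season)
        windows = scan.generate_windows(centroids, counts)
        clusters = scan.run_scan(counts, windows, n_sim=n_sim,
                                 seed=(seed * 999_983 + rep) % 2**31,
                                 alpha=0.05)
        if not clusters:
            overlaps.append(0.0)
            continue
        primary = scan.prune_low_rr_counties(clusters[0], counts)
        overlaps.append(jaccard(primary.counties, planted)
                        if primary else 0.0)
    ov = np.asarray(overlaps)
    return {"fraction_recovered": float((ov >= jaccard_threshold).mean()),
            "n_replicates": n_replicates, "event_days": event_days,
            "jaccard": ov}


def mars_recovery(n_replicates: int = 20, seed: int = 0,
                  n_counties: int = 100,
                  effects: dict[str, float] | None = None,
                  baseline_mean: float = 8.0) -> dict:
    """Fraction of replicates ranking the two planted drivers top-2.

    Each replicate draws a fresh covariate table (no planted mean shifts, so
    the 12 unused roster columns are pure noise), a Poisson response driven
    by the two named covariates, and a full MARS fit; success means the two
    drivers occupy the top-2 importance rows.  Also reports whether the top
    importance was exactly 100 in every replicate (it is by normalization
    whenever any variable enters).
    """
    if effects is None:
        effects = dict(DEFAULT_MARS_EFFECTS)
    side = int(np.ceil(np.sqrt(n_counties)))
    successes = []
    top_always_100 = True
    for rep in range(n_replicates):
        rep_seed = (seed * 777_767 + rep) % 2**31
        cfg = synthetic.SyntheticConfig(
            n_counties=n_counties, grid_shape=(side, side),
            covariate_effects={}, seed=rep_seed)
        counties = synthetic.make_counties(cfg)
        covs = synthetic.simulate_covariates(counties, cfg)
        y = synthetic.simulate_mars_response(
            covs.table, effects, baseline_mean=baseline_mean, seed=rep_seed)
        X = covs.table[list(COVARIATE_ROSTER)].to_numpy(dtype=float)
        model = mars.fit_mars(X, y, feature_names=list(COVARIATE_ROSTER))
        imp = model.importance
        if imp.empty:
            successes.append(False)
            continue
        top2 = set(imp["variable"].head(2))
        successes.append(top2 == set(effects))
        top_always_100 = top_always_100 and bool(
            np.isclose(imp["importance"].iloc[0], 100.0))
    return {"fraction_top2": float(np.mean(successes)),
            "n_replicates": n_replicates,
            "top_importance_always_100": top_always_100}


def t90_exceedance_percent(config: synthetic.SyntheticConfig | None = None,
                           ) -> dict:
    """Percent of climatology days above t90, per county, plus the mean."""
    cfg = config or synthetic.SyntheticConfig()
    counties = synthetic.make_counties(cfg)
    temps = synthetic.simulate_temperature(counties, cfg)
    daily = exposure.compute_thresholds(temps, cfg.climatology_years)
    years = pd.DatetimeIndex(temps["date"]).year
    clim = temps[(years >= cfg.climatology_years[0])
                 & (years <= cfg.climatology_years[1])]
    clim = exposure.drop_feb29(clim)
    t90 = exposure._threshold_arrays(daily, "t90")
    fracs = {}
    for county, g in clim.groupby("county_id"):
        doy = exposure.doy365(g["date"])
        fracs[county] = float(
            (g["tmean_c"].to_numpy() > t90[county][doy - 1]).mean() * 100)
    vals = np.array(list(fracs.values()))
    return {"per_county_percent": fracs, "mean_percent": float(vals.mean()),
            "min_percent": float(vals.min()),
            "max_percent": float(vals.max())}
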