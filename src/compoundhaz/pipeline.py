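"""End-to-end orchestration: inputs -> exposure -> scans -> interaction -> MARS.

``run_all`` executes the full analysis for each hazard (heatwave, drought,
compound) and outcome (mood, suicide): builds the county-day exposure
calendar, aggregates event-day cases versus non-event-day controls, scans for
high-risk spatial clusters, prunes non-elevated member counties, derives the
additive/multiplicative interaction record from the three primary-cluster
relative risks per outcome, and fits a MARS variable-importance model of
per-county outcome counts inside the high-risk clusters.

Outputs are plain CSV/JSON files in a run directory, with a manifest holding
the config hash and seeds; reruns with the same config and seeds are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import covariates as cov
from . import exposure, interaction, mars, scan, synthetic

logger = logging.getLogger(__name__)

HAZARDS = ("heatwave", "drought", "compound")


@dataclass
class RunConfig:
    """Configuration for a full synthetic run."""

    synthetic: synthetic.SyntheticConfig = field(
        default_factory=synthetic.SyntheticConfig)
    out_dir: str = "run"
    hazards: tuple[str, ...] = HAZARDS
    scan_max_fraction: float = 0.25
    scan_cap_on: str = "total"
    n_sim: int = 999
    alpha: float = 0.05
    scan_seed: int = 1
    mars_max_terms: int = 21
    mars_degree: int = 1
    mars_penalty: float = mars.DEFAULT_PENALTY
    mars_seed: int = 1
    #: model every county with a cluster-membership indicator predictor
    #: instead of cluster counties only
    mars_include_all: bool = False
    ice_variant: str = "racialized_economic"


def _hash_config(config: RunConfig) -> str:
    d = dataclasses.asdict(config)
    d["synthetic"] = synthetic.config_to_dict(config.synthetic)
    return hashlib.sha256(
        json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _cluster_record(cl: scan.Cluster) -> dict:
    return {"rank": cl.rank, "counties": list(cl.counties),
            "cases": cl.cases, "n": cl.n, "llr": round(cl.llr, 4),
            "rr": round(cl.rr, 4), "p_value": cl.p_value}


def build_exposure(temps: pd.DataFrame, usdm: pd.DataFrame,
                   config: synthetic.SyntheticConfig):
    """Thresholds, events, episodes and the analysis-years calendar."""
    thresholds = exposure.compute_all_thresholds(
        temps, config.climatology_years)
    y0, y1 = config.analysis_years
    dates = pd.DatetimeIndex(temps["date"])
    # 40-day lead so EHF has its 30-day acclimatization history
    lead = pd.Timestamp(f"{y0}-01-01") - pd.Timedelta(days=40)
    analysis = temps[(dates >= lead) & (dates <= pd.Timestamp(f"{y1}-12-31"))]
    events = exposure.detect_heatwaves(analysis, thresholds)
    ehf = exposure.compute_ehf(analysis, thresholds)
    events = exposure.flag_high_intensity(events, ehf, thresholds)
    episodes = exposure.build_drought_episodes(usdm)
    domain = pd.date_range(f"{y0}-01-01", f"{y1}-12-31", freq="D")
    domain = domain[~((domain.month == 2) & (domain.day == 29))]
    events = events[(events["end_date"] >= domain[0])
                    & (events["start_date"] <= domain[-1])]
    calendar = exposure.build_exposure_calendar(
        events, episodes, sorted(temps["county_id"].unique()), domain)
    return thresholds, events, episodes, calendar


def summarize_table2(clusters_by: dict) -> pd.DataFrame:
    """One row per hazard x outcome x cluster rank with scan statistics."""
    rows = []
    for (hazard, outcome), clusters in sorted(clusters_by.items()):
        for cl in clusters:
            rows.append({
                "hazard": hazard, "outcome": outcome, "rank": cl.rank,
                "cases": cl.cases, "llr": cl.llr,
                "n_counties": len(cl.counties), "p_value": cl.p_value,
                "rr": cl.rr})
    return pd.DataFrame(rows, columns=["hazard", "outcome", "rank", "cases",
                                       "llr", "n_counties", "p_value", "rr"])


def interaction_from_primaries(primaries: dict) -> dict:
    """Interaction record from the heatwave/drought/compound primary RRs.

    ``primaries`` maps hazard -> primary Cluster or None.  When any of the
    three scans lacks a significant primary cluster the record carries an
    explicit not-estimable flag instead of values.
    """
    missing = [h for h in HAZARDS if primaries.get(h) is None]
    if missing:
        return {"estimable": False, "missing_hazards": missing}
    t = interaction.RiskTriple(rr10=primaries["heatwave"].rr,
                               rr01=primaries["drought"].rr,
                               rr11=primaries["compound"].rr)
    rec = interaction.measures_record(t)
    rec["estimable"] = True
    return rec


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns the machine-readable summary dict."""
    t_start = time.time()
    out = Path(config.out_dir)
    (out / "inputs").mkdir(parents=True, exist_ok=True)
    syn = config.synthetic

    logger.info("stage 1/6: generating synthetic inputs")
    counties = synthetic.make_counties(syn)
    temps = synthetic.simulate_temperature(counties, syn)
    usdm = synthetic.simulate_usdm(counties, syn)
    covs = synthetic.simulate_covariates(counties, syn)
    synthetic.write_counties_csv(counties, out / "inputs" / "counties.csv")
    synthetic.write_temperature_csv(temps, out / "inputs" / "temperature.csv")
    synthetic.write_usdm_csv(usdm, out / "inputs" / "usdm.csv")
    cov.write_covariates_csv(covs.table, out / "inputs" / "covariates.csv")
    synthetic.write_centroids_geojson(counties, out / "inputs"
                                      / "centroids.geojson")
    synthetic.write_config_yaml(syn, out / "inputs" / "synthetic_config.yaml")

    logger.info("stage 2/6: exposure calendar")
    thresholds, events, episodes, calendar = build_exposure(temps, usdm, syn)
    exposure.write_calendar_csv(calendar, out / "exposure_calendar.csv")

    logger.info("stage 3/6: visit simulation")
    visits = synthetic.simulate_visits(counties, calendar, syn)
    synthetic.write_visits_csv(visits, out / "inputs" / "visits.csv")

    logger.info("stage 4/6: Bernoulli scans")
    centroids = counties[["county_id", "x_km", "y_km"]]
    clusters_by: dict = {}
    scan_status: dict = {}
    labeled_frames = []
    for hi, hazard in enumerate(config.hazards):
        for oi, outcome in enumerate(syn.outcomes):
            key = (hazard, outcome)
            counts = scan.aggregate_case_control(
                visits, calendar, hazard, outcome, season=syn.warm_season)
            if counts["cases"].sum() < 1:
                logger.warning("%s/%s: no cases; scan skipped", hazard,
                               outcome)
                clusters_by[key] = []
                scan_status[key] = "no cases"
                continue
            try:
                windows = scan.generate_windows(
                    centroids, counts, max_fraction=config.scan_max_fraction,
                    cap_on=config.scan_cap_on)
            except scan.WindowConfigError as err:
                logger.warning("%s/%s: %s", hazard, outcome, err)
                clusters_by[key] = []
                scan_status[key] = "no windows"
                continue
            found = scan.run_scan(
                counts, windows, n_sim=config.n_sim,
                seed=config.scan_seed + 101 * hi + 11 * oi,
                alpha=config.alpha)
            pruned = [p for cl in found
                      if (p := scan.prune_low_rr_counties(cl, counts))
                      is not None]
            clusters_by[key] = pruned
            scan_status[key] = "ok"
            lab = scan.label_visits(
                visits[visits["outcome"] == outcome], pruned)
            lab.insert(0, "hazard", hazard)
            labeled_frames.append(lab)
    summarize_table2(clusters_by).to_csv(out / "clusters_table2.csv",
                                         index=False)
    if labeled_frames:
        labeled = pd.concat(labeled_frames, ignore_index=True)
        synthetic.write_visits_csv(labeled, out / "labeled_visits.csv")

    logger.info("stage 5/6: interaction measures")
    interactions = {}
    for outcome in syn.outcomes:
        primaries = {
            h: next((cl for cl in clusters_by.get((h, outcome), [])
                     if cl.rank == 1), None)
            for h in HAZARDS}
        interactions[outcome] = interaction_from_primaries(primaries)

    logger.info("stage 6/6: MARS variable importance")
    mars_reports: dict = {}
    for hazard in config.hazards:
        for outcome in syn.outcomes:
            key = (hazard, outcome)
            high = sorted({c for cl in clusters_by.get(key, [])
                           for c in cl.counties})
            v = visits[visits["outcome"] == outcome]
            counts_by_county = v.groupby("county_id").size()
            fitted = mars.fit_cluster_model(
                covs.table[["county_id"] + list(cov.COVARIATE_ROSTER)],
                high, counts_by_county, seed=config.mars_seed,
                include_all_counties=config.mars_include_all,
                max_terms=config.mars_max_terms,
                max_degree=config.mars_degree, penalty=config.mars_penalty)
            name = f"{hazard}_{outcome}"
            if fitted is None:
                mars_reports[name] = {"status": "skipped: fewer than 2"
                                               " cluster counties"}
                continue
            model, report = fitted
            model.importance.to_csv(out / f"importance_{name}.csv",
                                    index=False)
            report["status"] = "ok"
            report["importance"] = [
                {"variable": r.variable, "bases": int(r.bases),
                 "importance": round(float(r.importance), 2)}
                for r in model.importance.itertuples()]
            mars_reports[name] = report

    summary = {
        "clusters": {f"{h}_{o}": {
            "status": scan_status.get((h, o), "ok"),
            "clusters": [_cluster_record(cl)
                         for cl in clusters_by.get((h, o), [])]}
            for h in config.hazards for o in syn.outcomes},
        "interaction": interactions,
        "mars": {k: {kk: vv for kk, vv in v.items()}
                 for k, v in mars_reports.items()},
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=float)
    manifest = {
        "config_hash": _hash_config(config),
        "seeds": {"synthetic": syn.seed, "scan": config.scan_seed,
                  "mars": config.mars_seed},
        "n_sim": config.n_sim,
        "stages": ["inputs", "exposure", "visits", "scan", "interaction",
                   "mars"],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    logger.info("run complete in %.1f s", time.time() - t_start)
    return summary
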