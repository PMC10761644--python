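"""County-day climate exposure construction.

Turns daily county mean temperature and weekly drought-category series into a
county-day calendar of heatwave, drought and compound (co-occurring) exposure
flags, plus the excess heat factor (EHF) used to grade heatwave intensity.

Definitions
-----------
* A day-of-year temperature climatology is built per county with a centered
  31-day moving window pooled over all climatology years: the threshold for
  May 1 pools April 15 - May 15 of every year.  The 90th percentile (t90)
  defines heatwaves; the 95th (t95) enters the EHF.
* A heatwave event begins on the first of 3 consecutive days with temperature
  strictly above t90 and ends on the last above-threshold day that is followed
  by 3 consecutive days at or below t90 (or by the end of the series).  Every
  day between start and end is a heatwave day, including short sub-threshold
  dips inside the event.
* A drought episode begins the first week at category D1 (moderate) or worse
  and ends at the last >=D1 week followed by 3 consecutive weeks of None/D0
  (or series end).  Every day of every week inside the episode is a drought
  day.
* A compound day is a day that is simultaneously a heatwave day and a drought
  day in the same county.  Multiple heatwaves inside a single drought are kept
  as separate compound spells.
* EHF for day i uses the forward three-day mean (days i, i+1, i+2):
  ``ehi_sig = mean3 - t95(doy_i)``, ``ehi_accl = mean3 - mean(prior 30 days)``,
  ``ehf = ehi_sig * max(1, ehi_accl)`` (units degC^2).  A heatwave event is
  high-intensity when any of its days has EHF at or above the county's 85th
  percentile of positive climatological EHF values.

February 29 is dropped before day-of-year indexing; percentiles use linear
interpolation between order statistics; exceedance is strict (ties at the
threshold do not count).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

USDM_CATEGORIES = ("None", "D0", "D1", "D2", "D3", "D4")
CATEGORY_LEVEL = {c: i for i, c in enumerate(USDM_CATEGORIES)}
#: minimum ordinal level counting as "in drought"
DROUGHT_LEVEL = CATEGORY_LEVEL["D1"]

#: calendar column holding each hazard's county-day flag
HAZARD_COLUMNS = {
    "heatwave": "heatwave_day",
    "drought": "drought_day",
    "compound": "compound_day",
    "heatwave_high": "high_intensity_day",
    "compound_high": "compound_high_day",
}

CALENDAR_COLUMNS = [
    "county_id", "date", "heatwave_day", "drought_day", "compound_day",
    "high_intensity_day", "compound_high_day",
]


class MissingDataError(ValueError):
    """An empty climatology window or a series/threshold domain hole."""


class AlignmentError(ValueError):
    """Inputs do not share the required county/date domain."""


class CategoryError(ValueError):
    """Unknown drought category string."""


def drop_feb29(df: pd.DataFrame, date_col: str = "date") -> pd.DataFrame:
    d = pd.DatetimeIndex(df[date_col])
    return df[~((d.month == 2) & (d.day == 29))]


def doy365(dates) -> np.ndarray:
    """Day-of-year on a 365-day calendar (Feb 29 must already be dropped)."""
    d = pd.DatetimeIndex(dates)
    doy = d.dayofyear.to_numpy().copy()
    doy[d.is_leap_year & (doy > 59)] -= 1
    return doy


@dataclass
class ClimatologyThresholds:
    """Per-county day-of-year thresholds plus the EHF severity cutoff.

    ``daily`` has columns county_id, doy (1..365), t90, t95.
    ``ehf_severity`` maps county_id -> 85th percentile of positive EHF over
    the climatology (NaN when the county never had positive EHF).
    """

    daily: pd.DataFrame
    ehf_severity: pd.Series


def compute_thresholds(temps: pd.DataFrame,
                       climatology_years: tuple[int, int],
                       window_days: int = 31,
                       percentiles: tuple[float, float] = (90.0, 95.0),
                       ) -> pd.DataFrame:
    """Day-of-year t90/t95 per county from a centered cyclic window.

    For each county and each day-of-year d, the percentile is taken over the
    multiset of temperatures on days within ``window_days//2`` of d
    (cyclically, so late-December windows wrap into January) across all
    climatology years.
    """
    lo, hi = climatology_years
    years = pd.DatetimeIndex(temps["date"]).year
    t = temps[(years >= lo) & (years <= hi)]
    if t.empty:
        raise MissingDataError(
            f"no temperature observations in climatology years {lo}-{hi}")
    t = drop_feb29(t)
    half = window_days // 2
    p_lo, p_hi = percentiles
    rows = []
    for county, g in t.groupby("county_id", sort=True):
        doy = doy365(g["date"])
        vals = g["tmean_c"].to_numpy(dtype=float)
        by_doy = [vals[doy == d] for d in range(1, 366)]
        for d in range(1, 366):
            pool = np.concatenate(
                [by_doy[(d - 1 + off) % 365] for off in range(-half, half + 1)])
            pool = pool[np.isfinite(pool)]
            if pool.size == 0:
                raise MissingDataError(
                    f"empty climatology window for county {county},"
                    f" day-of-year {d}")
            t_lo, t_hi = np.percentile(pool, [p_lo, p_hi])
            rows.append((county, d, t_lo, t_hi))
    return pd.DataFrame(rows, columns=["county_id", "doy", "t90", "t95"])


def compute_all_thresholds(temps: pd.DataFrame,
                           climatology_years: tuple[int, int],
                           window_days: int = 31,
                           ) -> ClimatologyThresholds:
    """t90/t95 day-of-year thresholds plus the per-county EHF severity cutoff
    (85th percentile of positive EHF over the climatology period)."""
    daily = compute_thresholds(temps, climatology_years, window_days)
    lo, hi = climatology_years
    years = pd.DatetimeIndex(temps["date"]).year
    clim = temps[(years >= lo) & (years <= hi)]
    ehf = compute_ehf(clim, daily)
    sev = {}
    for county in daily["county_id"].unique():
        pos = ehf.loc[(ehf["county_id"] == county) & (ehf["ehf"] > 0), "ehf"]
        if pos.empty:
            logger.warning(
                "county %s has no positive EHF in climatology;"
                " severity threshold undefined", county)
            sev[county] = np.nan
        else:
            sev[county] = float(np.percentile(pos.to_numpy(), 85.0))
    return ClimatologyThresholds(
        daily=daily, ehf_severity=pd.Series(sev, name="ehf_severity"))


def _threshold_arrays(daily: pd.DataFrame, col: str) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for county, g in daily.groupby("county_id"):
        arr = np.full(365, np.nan)
        arr[g["doy"].to_numpy() - 1] = g[col].to_numpy(dtype=float)
        out[county] = arr
    return out


def _county_daily_series(g: pd.DataFrame):
    """Contiguous daily values (Feb 29 dropped, gaps as NaN) for one county."""
    g = drop_feb29(g).sort_values("date")
    dates = pd.DatetimeIndex(g["date"])
    full = pd.date_range(dates[0], dates[-1], freq="D")
    full = full[~((full.month == 2) & (full.day == 29))]
    s = pd.Series(g["tmean_c"].to_numpy(dtype=float), index=dates).reindex(full)
    return full, s.to_numpy()


def _runs_of_true(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as inclusive (start, end) index pairs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    return [(int(idx[a]), int(idx[b])) for a, b in zip(starts, ends)]


def _events_from_mask(mask: np.ndarray, min_run: int,
                      max_gap: int = 2) -> list[tuple[int, int]]:
    """Event spans from a boolean exceedance mask.

    Runs of True separated by gaps of at most ``max_gap`` False steps chain
    together; the event starts at the first run in the chain of length at
    least ``min_run`` and ends at the chain's last True step (a longer gap,
    or the series end, terminates the event).
    """
    events: list[tuple[int, int]] = []
    chain: list[tuple[int, int]] = []

    def close(chain):
        for a, b in chain:
            if b - a + 1 >= min_run:
                return (a, chain[-1][1])
        return None

    for run in _runs_of_true(mask):
        if chain and run[0] - chain[-1][1] - 1 <= max_gap:
            chain.append(run)
        else:
            if (ev := close(chain)) is not None:
                events.append(ev)
            chain = [run]
    if (ev := close(chain)) is not None:
        events.append(ev)
    return events


def detect_heatwaves(temps: pd.DataFrame,
                     thresholds: ClimatologyThresholds | pd.DataFrame,
                     ) -> pd.DataFrame:
    """Heatwave events per county.

    Returns a frame with columns county_id, start_date, end_date (inclusive),
    high_intensity (False; set by :func:`flag_high_intensity`).  Gaps in the
    series are treated as below threshold and logged.
    """
    daily = thresholds.daily if isinstance(thresholds, ClimatologyThresholds) \
        else thresholds
    t90 = _threshold_arrays(daily, "t90")
    events = []
    for county, g in temps.groupby("county_id", sort=True):
        if county not in t90:
            raise MissingDataError(f"no thresholds for county {county}")
        full, vals = _county_daily_series(g)
        n_gap = int(np.isnan(vals).sum())
        if n_gap:
            logger.warning("county %s: %d missing days treated as"
                           " below threshold", county, n_gap)
        thr = t90[county][doy365(full) - 1]
        above = np.greater(vals, thr, where=~np.isnan(vals),
                           out=np.zeros(len(vals), dtype=bool))
        for a, b in _events_from_mask(above, min_run=3):
            events.append((county, full[a], full[b], False))
    return pd.DataFrame(
        events, columns=["county_id", "start_date", "end_date",
                         "high_intensity"])


def compute_ehf(temps: pd.DataFrame,
                thresholds: ClimatologyThresholds | pd.DataFrame,
                ) -> pd.DataFrame:
    """Daily excess heat factor per county.

    Day i is scored when the forward three-day mean (i, i+1, i+2) and the full
    prior-30-day mean exist; earlier days are skipped (logged once per
    county).
    """
    daily = thresholds.daily if isinstance(thresholds, ClimatologyThresholds) \
        else thresholds
    t95 = _threshold_arrays(daily, "t95")
    frames = []
    for county, g in temps.groupby("county_id", sort=True):
        if county not in t95:
            raise MissingDataError(f"no thresholds for county {county}")
        full, vals = _county_daily_series(g)
        s = pd.Series(vals)
        mean3 = s.rolling(3).mean().shift(-2).to_numpy()
        prior30 = s.rolling(30).mean().shift(1).to_numpy()
        thr = t95[county][doy365(full) - 1]
        ehi_sig = mean3 - thr
        ehi_accl = mean3 - prior30
        ehf = ehi_sig * np.maximum(1.0, ehi_accl)
        ok = np.isfinite(ehi_sig) & np.isfinite(ehi_accl)
        if (~ok).sum():
            logger.debug("county %s: %d days skipped for EHF (insufficient"
                         " history or gaps)", county, int((~ok).sum()))
        frames.append(pd.DataFrame({
            "county_id": county, "date": full[ok], "ehi_sig": ehi_sig[ok],
            "ehi_accl": ehi_accl[ok], "ehf": ehf[ok]}))
    if not frames:
        return pd.DataFrame(
            columns=["county_id", "date", "ehi_sig", "ehi_accl", "ehf"])
    return pd.concat(frames, ignore_index=True)


def flag_high_intensity(events: pd.DataFrame, ehf_daily: pd.DataFrame,
                        thresholds: ClimatologyThresholds) -> pd.DataFrame:
    """Mark events containing any day with EHF >= the county severity cutoff."""
    out = events.copy()
    flags = []
    for _, ev in out.iterrows():
        sev = thresholds.ehf_severity.get(ev["county_id"], np.nan)
        if not np.isfinite(sev):
            logger.warning("county %s: EHF severity undefined; event at %s"
                           " kept low-intensity", ev["county_id"],
                           ev["start_date"].date())
            flags.append(False)
            continue
        day_ehf = ehf_daily[
            (ehf_daily["county_id"] == ev["county_id"])
            & (ehf_daily["date"] >= ev["start_date"])
            & (ehf_daily["date"] <= ev["end_date"])]["ehf"]
        flags.append(bool((day_ehf >= sev).any()))
    out["high_intensity"] = flags
    return out


def build_drought_episodes(usdm: pd.DataFrame) -> pd.DataFrame:
    """Drought episodes per county from weekly USDM categories.

    ``usdm`` has columns county_id, week_start, category.  Weeks must be
    contiguous (7-day spacing) per county.  Returns columns county_id,
    start_week, end_week (inclusive week-start dates).
    """
    bad = set(usdm["category"]) - set(USDM_CATEGORIES)
    if bad:
        raise CategoryError(f"unknown drought categories: {sorted(bad)}")
    episodes = []
    for county, g in usdm.groupby("county_id", sort=True):
        g = g.sort_values("week_start")
        weeks = pd.DatetimeIndex(g["week_start"])
        if len(weeks) > 1 and not (np.diff(weeks.to_numpy())
                                   == np.timedelta64(7, "D")).all():
            raise AlignmentError(f"county {county}: weeks not contiguous")
        level = g["category"].map(CATEGORY_LEVEL).to_numpy()
        in_drought = level >= DROUGHT_LEVEL
        for a, b in _events_from_mask(in_drought, min_run=1):
            episodes.append((county, weeks[a], weeks[b]))
    return pd.DataFrame(episodes,
                        columns=["county_id", "start_week", "end_week"])


def expand_drought_days(episodes: pd.DataFrame) -> pd.DataFrame:
    """All 7 days of every week inside each episode, flagged as drought days."""
    frames = []
    for _, ep in episodes.iterrows():
        days = pd.date_range(ep["start_week"],
                             ep["end_week"] + pd.Timedelta(days=6), freq="D")
        frames.append(pd.DataFrame({"county_id": ep["county_id"],
                                    "date": days}))
    if not frames:
        return pd.DataFrame(columns=["county_id", "date"])
    return pd.concat(frames, ignore_index=True)


def build_exposure_calendar(events: pd.DataFrame, episodes: pd.DataFrame,
                            counties, dates) -> pd.DataFrame:
    """County-day exposure flags on an explicit county x date domain.

    ``compound_day`` is the per-cell conjunction of heatwave and drought
    flags; ``compound_high_day`` additionally requires the heatwave day to
    belong to a high-intensity event.
    """
    counties = list(counties)
    dates = pd.DatetimeIndex(dates).sort_values()
    known = set(counties)
    for frame, name in ((events, "heatwave events"),
                        (episodes, "drought episodes")):
        extra = set(frame["county_id"]) - known
        if extra:
            raise AlignmentError(
                f"{name} reference counties outside the calendar domain:"
                f" {sorted(extra)}")
    idx = pd.MultiIndex.from_product([counties, dates],
                                     names=["county_id", "date"])
    cal = pd.DataFrame(False, index=idx,
                       columns=["heatwave_day", "drought_day",
                                "high_intensity_day"])
    for _, ev in events.iterrows():
        span = dates[(dates >= ev["start_date"]) & (dates <= ev["end_date"])]
        cal.loc[(ev["county_id"], span), "heatwave_day"] = True
        if ev["high_intensity"]:
            cal.loc[(ev["county_id"], span), "high_intensity_day"] = True
    drought = expand_drought_days(episodes)
    if not drought.empty:
        in_domain = pd.MultiIndex.from_frame(drought[["county_id", "date"]])
        in_domain = in_domain[in_domain.isin(idx)]
        cal.loc[in_domain, "drought_day"] = True
    cal["compound_day"] = cal["heatwave_day"] & cal["drought_day"]
    cal["compound_high_day"] = cal["high_intensity_day"] & cal["drought_day"]
    return cal.reset_index()[CALENDAR_COLUMNS]


def compound_spells(events: pd.DataFrame,
                    episodes: pd.DataFrame) -> pd.DataFrame:
    """Event-level compound bookkeeping.

    Each heatwave event overlapping a drought episode in the same county
    yields its own compound spell, so two heatwaves inside one drought are two
    separate spells.
    """
    rows = []
    for county, evs in events.groupby("county_id"):
        eps = episodes[episodes["county_id"] == county]
        for _, ev in evs.iterrows():
            for _, ep in eps.iterrows():
                drought_end = ep["end_week"] + pd.Timedelta(days=6)
                first = max(ev["start_date"], ep["start_week"])
                last = min(ev["end_date"], drought_end)
                if first <= last:
                    rows.append((county, ev["start_date"], ev["end_date"],
                                 ep["start_week"], ep["end_week"], first,
                                 last, (last - first).days + 1))
    return pd.DataFrame(rows, columns=[
        "county_id", "heatwave_start", "heatwave_end", "drought_start_week",
        "drought_end_week", "first_day", "last_day", "n_days"])


def write_calendar_csv(calendar: pd.DataFrame, path) -> None:
    out = calendar.copy()
    out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_calendar_csv(path) -> pd.DataFrame:
    cal = pd.read_csv(path, parse_dates=["date"])
    for col in CALENDAR_COLUMNS[2:]:
        cal[col] = cal[col].astype(bool)
    return cal
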