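"""Exposure-rule tests: climatology thresholds, heatwave/drought events, EHF.

The heatwave and drought detectors are checked against independent
brute-force re-implementations of the event rules (written here, forward
scanning with explicit termination counting, unlike the package's run-chain
algorithm).
"""

import numpy as np
import pandas as pd
import pytest

from compoundhaz import exposure
from conftest import make_thresholds_frame, temps_frame


# ---------------------------------------------------------------------------
# independent brute-force oracles for the event rules

def oracle_heatwave_events(above):
    """Forward scan: start at 3 consecutive above; end after 3 consecutive
    at-or-below (or series end)."""
    events = []
    n = len(above)
    i = 0
    while i < n:
        if i + 2 < n and above[i] and above[i + 1] and above[i + 2]:
            last = i + 2
            below = 0
            j = i + 3
            while j < n and below < 3:
                if above[j]:
                    last = j
                    below = 0
                else:
                    below += 1
                j += 1
            events.append((i, last))
            i = last + 1
        else:
            i += 1
    return events


def oracle_drought_episodes(in_drought):
    """Same forward scan with a 1-week start requirement."""
    episodes = []
    n = len(in_drought)
    i = 0
    while i < n:
        if in_drought[i]:
            last = i
            below = 0
            j = i + 1
            while j < n and below < 3:
                if in_drought[j]:
                    last = j
                    below = 0
                else:
                    below += 1
                j += 1
            episodes.append((i, last))
            i = last + 1
        else:
            i += 1
    return episodes


# ---------------------------------------------------------------------------
# climatology thresholds

def test_constant_series_thresholds_are_the_constant():
    temps = temps_frame("X", "2000-01-01", [20.0] * (365 * 2 + 1))
    daily = exposure.compute_thresholds(temps, (2000, 2001))
    assert (daily["t90"] == 20.0).all()
    assert (daily["t95"] == 20.0).all()
    assert len(daily) == 365


def test_threshold_matches_brute_force_window_percentile():
    """Percentile equals an order-statistic computation over the explicitly
    enumerated 31-day x all-years multiset, including the cyclic wrap."""
    rng = np.random.default_rng(5)
    n_years = 3
    dates = pd.date_range("2000-01-01", "2002-12-31", freq="D")
    dates = dates[~((dates.month == 2) & (dates.day == 29))]
    vals = rng.normal(15.0, 6.0, len(dates))
    temps = pd.DataFrame({"county_id": "X", "date": dates, "tmean_c": vals})
    daily = exposure.compute_thresholds(temps, (2000, 2002))
    by_day = dict(zip(dates, vals))
    # each year's 365 dates with Feb 29 dropped: entry d-1 is day-of-year d
    year_days = {}
    for year in range(2000, 2000 + n_years):
        yd = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
        year_days[year] = yd[~((yd.month == 2) & (yd.day == 29))]
    for doy in (1, 17, 121, 200, 362, 365):  # includes Dec wrap into January
        pool = []
        for year, yd in year_days.items():
            for off in range(-15, 16):
                pool.append(by_day[yd[(doy - 1 + off) % 365]])
        row = daily[daily["doy"] == doy].iloc[0]
        assert row["t90"] == pytest.approx(np.percentile(pool, 90), abs=1e-9)
        assert row["t95"] == pytest.approx(np.percentile(pool, 95), abs=1e-9)


def test_empty_window_raises_named_error():
    temps = temps_frame("X", "2000-06-01", [20.0] * 10)
    with pytest.raises(exposure.MissingDataError, match="county X"):
        exposure.compute_thresholds(temps, (2000, 2000))


def test_t95_at_least_t90_everywhere(fast_system):
    _, _, _, thresholds, _, _, _ = fast_system
    assert (thresholds.daily["t95"] >= thresholds.daily["t90"]).all()


# ---------------------------------------------------------------------------
# heatwave detection (hand traces from the event-rule definition)

@pytest.mark.parametrize("values,expected_spans", [
    # one event days 1-5: dip on day 4 is inside, 3 below days end it
    ([31, 32, 33, 29, 31, 28, 27, 26], [(0, 4)]),
    # never 3 consecutive above -> no event
    ([31, 32, 29, 31, 32, 29, 31, 32, 29], []),
    # series end closes the event
    ([31, 32, 33], [(0, 2)]),
    # 2-day run before the qualifying run is not part of the event
    ([31, 32, 29, 29, 31, 32, 33, 28, 28, 28], [(4, 6)]),
    # threshold ties do not count (strict exceedance)
    ([30, 30, 30, 30], []),
], ids=["dip-inside", "no-persistence", "series-end", "late-qualify", "ties"])
def test_heatwave_hand_traces(values, expected_spans):
    thr = make_thresholds_frame("X", t90=30.0, t95=31.0)
    temps = temps_frame("X", "2021-06-01", values)
    events = exposure.detect_heatwaves(temps, thr)
    spans = [((ev.start_date - pd.Timestamp("2021-06-01")).days,
              (ev.end_date - pd.Timestamp("2021-06-01")).days)
             for ev in events.itertuples()]
    assert spans == expected_spans


def test_detector_matches_brute_force_on_random_series():
    rng = np.random.default_rng(12)
    thr = make_thresholds_frame("X", t90=0.0, t95=1.0)
    for _ in range(50):
        vals = rng.normal(0.0, 1.0, 60)
        temps = temps_frame("X", "2021-03-01", vals)
        events = exposure.detect_heatwaves(temps, thr)
        got = [((ev.start_date - pd.Timestamp("2021-03-01")).days,
                (ev.end_date - pd.Timestamp("2021-03-01")).days)
               for ev in events.itertuples()]
        assert got == oracle_heatwave_events(vals > 0.0)


def test_gap_days_treated_as_below_threshold(caplog):
    thr = make_thresholds_frame("X", t90=30.0, t95=31.0)
    temps = temps_frame("X", "2021-06-01", [31, 32, 33, 31, 31, 31])
    # remove 3 days inside: the gap terminates the event
    temps = temps.drop(index=[3, 4, 5])
    more = temps_frame("X", "2021-06-07", [31.0])
    temps = pd.concat([temps, more], ignore_index=True)
    with caplog.at_level("WARNING"):
        events = exposure.detect_heatwaves(temps, thr)
    assert len(events) == 1
    assert events.iloc[0]["end_date"] == pd.Timestamp("2021-06-03")
    assert "missing days" in caplog.text


def test_pure_sinusoid_exceedances_confined_to_seasonal_peak():
    """With zero noise the only t90 exceedances are the exact-tie days at
    the annual peak (the center day of the warmest window is above its own
    window's 90th percentile by construction), so any detected event sits in
    the immediate peak neighbourhood."""
    from compoundhaz import synthetic
    cfg = synthetic.SyntheticConfig(
        n_counties=1, grid_shape=(1, 1), noise_sd_c=0.0, hot_spell_rate=0.0,
        climatology_years=(2000, 2003), analysis_years=(2004, 2004), seed=0)
    counties = synthetic.make_counties(cfg)
    temps = synthetic.simulate_temperature(counties, cfg)
    daily = exposure.compute_thresholds(temps, (2000, 2003))
    yr = temps[pd.DatetimeIndex(temps["date"]).year == 2004]
    events = exposure.detect_heatwaves(yr, daily)
    for ev in events.itertuples():
        assert abs(exposure.doy365([ev.start_date])[0] - cfg.peak_doy) <= 3
        assert abs(exposure.doy365([ev.end_date])[0] - cfg.peak_doy) <= 3


# ---------------------------------------------------------------------------
# EHF

def test_ehf_direct_formula():
    # 30 days at 25, then 3 days at 30: day 31 has mean3=30, prior=25
    vals = [25.0] * 30 + [30.0] * 3
    temps = temps_frame("X", "2021-05-01", vals)
    thr = make_thresholds_frame("X", t90=27.0, t95=28.0)
    ehf = exposure.compute_ehf(temps, thr)
    day31 = ehf[ehf["date"] == pd.Timestamp("2021-05-31")].iloc[0]
    assert day31["ehi_sig"] == pytest.approx(2.0)
    assert day31["ehi_accl"] == pytest.approx(5.0)
    assert day31["ehf"] == pytest.approx(10.0)


def test_ehf_acclimatization_floor():
    # prior mean 29.5, three-day mean 30 -> accl 0.5 -> floor at 1
    vals = [29.5] * 30 + [30.0] * 3
    temps = temps_frame("X", "2021-05-01", vals)
    thr = make_thresholds_frame("X", t90=27.0, t95=28.0)
    ehf = exposure.compute_ehf(temps, thr)
    day31 = ehf[ehf["date"] == pd.Timestamp("2021-05-31")].iloc[0]
    assert day31["ehi_accl"] == pytest.approx(0.5)
    assert day31["ehf"] == pytest.approx(day31["ehi_sig"])
    assert day31["ehf"] == pytest.approx(2.0)


def test_constant_series_has_no_positive_ehf():
    temps = temps_frame("X", "2021-05-01", [20.0] * 60)
    thr = make_thresholds_frame("X", t90=20.0, t95=20.0)
    ehf = exposure.compute_ehf(temps, thr)
    assert (ehf["ehf"] <= 0).all()
    assert ((ehf["ehf"] > 0) <= (ehf["ehi_sig"] > 0)).all()


def test_high_intensity_boundary_and_planted_spell(fast_system):
    counties, temps, _, thresholds, events, _, _ = fast_system
    # boundary convention: ehf == threshold counts as high intensity
    cid = counties["county_id"].iloc[0]
    sev = float(thresholds.ehf_severity[cid])
    ev = pd.DataFrame({"county_id": [cid],
                       "start_date": [pd.Timestamp("2006-06-01")],
                       "end_date": [pd.Timestamp("2006-06-04")],
                       "high_intensity": [False]})
    ehf_daily = pd.DataFrame({"county_id": [cid],
                              "date": [pd.Timestamp("2006-06-02")],
                              "ehi_sig": [1.0], "ehi_accl": [sev],
                              "ehf": [sev]})
    flagged = exposure.flag_high_intensity(ev, ehf_daily, thresholds)
    assert bool(flagged.iloc[0]["high_intensity"])
    # all days at or below zero EHF -> low intensity
    ehf_daily2 = ehf_daily.assign(ehf=-1.0)
    assert not exposure.flag_high_intensity(
        ev, ehf_daily2, thresholds).iloc[0]["high_intensity"]


def test_extreme_planted_spell_is_high_intensity():
    """A +10 degC 5-day spell on a mild background produces EHF far above
    the 85th percentile of climatological positive EHF."""
    from compoundhaz import synthetic
    cfg = synthetic.SyntheticConfig(
        n_counties=1, grid_shape=(1, 1), noise_sd_c=1.0, ar1_rho=0.5,
        hot_spell_rate=0.5, hot_spell_magnitude_c=2.0,
        climatology_years=(2000, 2005), analysis_years=(2006, 2006), seed=4)
    counties = synthetic.make_counties(cfg)
    temps = synthetic.simulate_temperature(counties, cfg)
    spell = (pd.DatetimeIndex(temps["date"]) >= "2006-06-10") & \
            (pd.DatetimeIndex(temps["date"]) <= "2006-06-14")
    temps.loc[spell, "tmean_c"] += 10.0
    thresholds = exposure.compute_all_thresholds(temps, (2000, 2005))
    yr = temps[pd.DatetimeIndex(temps["date"]).year == 2006]
    events = exposure.detect_heatwaves(yr, thresholds)
    ehf = exposure.compute_ehf(temps, thresholds)
    events = exposure.flag_high_intensity(events, ehf, thresholds)
    hit = events[(events["start_date"] <= "2006-06-10")
                 & (events["end_date"] >= "2006-06-14")]
    assert len(hit) == 1
    assert bool(hit.iloc[0]["high_intensity"])


# ---------------------------------------------------------------------------
# drought episodes

def _usdm_frame(cats, county="X", start="2021-01-05"):
    weeks = pd.date_range(start, periods=len(cats), freq="7D")
    return pd.DataFrame({"county_id": county, "week_start": weeks,
                         "category": cats})


@pytest.mark.parametrize("cats,expected_weeks,expected_days", [
    (["None", "D1", "D2", "D0", "D0", "D0", "None"], [(1, 2)], 14),
    (["D1", "D0", "D1", "D0", "D0", "D0"], [(0, 2)], 21),
    (["D0", "D0", "None"], [], 0),
], ids=["one-episode", "dip-insufficient", "never-d1"])
def test_drought_episode_hand_traces(cats, expected_weeks, expected_days):
    usdm = _usdm_frame(cats)
    episodes = exposure.build_drought_episodes(usdm)
    weeks = pd.DatetimeIndex(usdm["week_start"])
    got = [((ep.start_week - weeks[0]).days // 7,
            (ep.end_week - weeks[0]).days // 7)
           for ep in episodes.itertuples()]
    assert got == expected_weeks
    assert len(exposure.expand_drought_days(episodes)) == expected_days


def test_one_episode_per_wet_dry_cycle():
    cats = ["None", "D1", "D2", "D0", "D0", "D0"] * 3 + ["None"]
    episodes = exposure.build_drought_episodes(_usdm_frame(cats))
    assert len(episodes) == 3


def test_drought_episodes_match_brute_force(fast_system):
    _, _, usdm, _, _, episodes, _ = fast_system
    for county, g in usdm.groupby("county_id"):
        g = g.sort_values("week_start")
        weeks = pd.DatetimeIndex(g["week_start"])
        level = g["category"].map(exposure.CATEGORY_LEVEL).to_numpy()
        want = oracle_drought_episodes(level >= exposure.DROUGHT_LEVEL)
        sub = episodes[episodes["county_id"] == county]
        got = [((ep.start_week - weeks[0]).days // 7,
                (ep.end_week - weeks[0]).days // 7)
               for ep in sub.itertuples()]
        assert got == want


def test_unknown_category_rejected():
    with pytest.raises(exposure.CategoryError, match="D5"):
        exposure.build_drought_episodes(_usdm_frame(["None", "D5"]))


def test_noncontiguous_weeks_rejected():
    usdm = _usdm_frame(["D1", "D1", "D1"])
    usdm.loc[2, "week_start"] += pd.Timedelta(days=7)
    with pytest.raises(exposure.AlignmentError):
        exposure.build_drought_episodes(usdm)


# ---------------------------------------------------------------------------
# calendar conjunction and compound spells

def _toy_events(county, spans):
    return pd.DataFrame([
        {"county_id": county, "start_date": pd.Timestamp(a),
         "end_date": pd.Timestamp(b), "high_intensity": False}
        for a, b in spans])


def test_calendar_compound_is_intersection():
    events = _toy_events("X", [("2021-06-05", "2021-06-09")])
    episodes = pd.DataFrame({"county_id": ["X"],
                             "start_week": [pd.Timestamp("2021-06-01")],
                             "end_week": [pd.Timestamp("2021-06-22")]})
    dates = pd.date_range("2021-06-01", "2021-06-30", freq="D")
    cal = exposure.build_exposure_calendar(events, episodes, ["X"], dates)
    assert cal["compound_day"].sum() == 5
    assert (cal["compound_day"] == (cal["heatwave_day"]
                                    & cal["drought_day"])).all()
    assert cal["heatwave_day"].sum() == 5
    assert cal["drought_day"].sum() == 28


def test_disjoint_spells_no_compound_days():
    events = _toy_events("X", [("2021-06-01", "2021-06-04")])
    episodes = pd.DataFrame({"county_id": ["X"],
                             "start_week": [pd.Timestamp("2021-07-06")],
                             "end_week": [pd.Timestamp("2021-07-13")]})
    dates = pd.date_range("2021-06-01", "2021-07-31", freq="D")
    cal = exposure.build_exposure_calendar(events, episodes, ["X"], dates)
    assert cal["compound_day"].sum() == 0


def test_two_heatwaves_in_one_drought_are_two_spells():
    events = _toy_events("X", [("2021-06-05", "2021-06-08"),
                               ("2021-06-15", "2021-06-18")])
    episodes = pd.DataFrame({"county_id": ["X"],
                             "start_week": [pd.Timestamp("2021-06-01")],
                             "end_week": [pd.Timestamp("2021-06-22")]})
    spells = exposure.compound_spells(events, episodes)
    assert len(spells) == 2
    assert spells["n_days"].tolist() == [4, 4]


def test_calendar_domain_mismatch_raises():
    events = _toy_events("Y", [("2021-06-05", "2021-06-09")])
    episodes = exposure.build_drought_episodes(_usdm_frame(["None"]))
    with pytest.raises(exposure.AlignmentError):
        exposure.build_exposure_calendar(
            events, episodes, ["X"],
            pd.date_range("2021-06-01", "2021-06-30"))


def test_calendar_invariants_on_synthetic_system(fast_system):
    _, _, _, _, _, _, cal = fast_system
    assert (cal["compound_day"] <= cal["heatwave_day"]).all()
    assert (cal["compound_day"] <= cal["drought_day"]).all()
    assert (cal["high_intensity_day"] <= cal["heatwave_day"]).all()


def test_calendar_csv_roundtrip(fast_system, tmp_path):
    _, _, _, _, _, _, cal = fast_system
    path = tmp_path / "cal.csv"
    exposure.write_calendar_csv(cal, path)
    back = exposure.read_calendar_csv(path)
    pd.testing.assert_frame_equal(back, cal.reset_index(drop=True))
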