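"""Bernoulli spatial scan statistic with elliptical windows.

Detects high-risk spatial clusters of event-day ED visits (cases) versus
non-event-day visits (controls) aggregated to counties.  Candidate windows
are the nested prefixes of counties ordered by elliptic distance from each
county centroid, over a grid of ellipse shapes and orientations (circles are
shape 1), capped at a fraction of the total observations.  Inference is by
Monte Carlo permutation of case labels over the fixed set of point locations,
conditional on the total case count.

The one-sided (high-risk) log-likelihood ratio for a window with c of n
points inside, out of C cases among N points, is::

    LLR = c ln(c/n) + (n-c) ln((n-c)/n)
        + (C-c) ln((C-c)/(N-n)) + ((N-n)-(C-c)) ln(((N-n)-(C-c))/(N-n))
        - [C ln(C/N) + (N-C) ln((N-C)/N)]     if c/n > (C-c)/(N-n), else 0

with 0 ln 0 = 0.  Cluster relative risk is (c/E) / ((C-c)/(C-E)) with
E = n C / N, the observed-over-expected ratio inside against outside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import xlogy

logger = logging.getLogger(__name__)

#: standard elliptic-scan grid: shape (major/minor axis ratio) -> angle count
DEFAULT_SHAPES = (1.0, 1.5, 2.0, 3.0, 4.0, 5.0)
DEFAULT_ANGLES = {1.0: 1, 1.5: 4, 2.0: 6, 3.0: 9, 4.0: 12, 5.0: 15}


class WindowConfigError(ValueError):
    """No scanning window survives the size cap."""


@dataclass(frozen=True)
class Cluster:
    """A reported high-risk cluster (rank 1 = primary)."""

    counties: tuple[str, ...]
    cases: int
    n: int
    llr: float
    rr: float
    p_value: float
    rank: int


def _llr_term(k, m):
    # k * ln(k/m) with the 0 ln 0 = 0 convention
    return xlogy(k, k) - xlogy(k, m)


def bernoulli_llr_vec(c, n, C, N):
    """Vectorized one-sided Bernoulli LLR (0 on the deficit side)."""
    c = np.asarray(c, dtype=float)
    n = np.asarray(n, dtype=float)
    inside = _llr_term(c, n) + _llr_term(n - c, n)
    out_n = N - n
    out_c = C - c
    outside = _llr_term(out_c, out_n) + _llr_term(out_n - out_c, out_n)
    null = _llr_term(float(C), float(N)) + _llr_term(float(N - C), float(N))
    llr = inside + outside - null
    high = (c * out_n > out_c * n) & (n > 0) & (n < N)
    return np.where(high, llr, 0.0)


def bernoulli_llr(c: int, n: int, C: int, N: int) -> float:
    """One-sided Bernoulli log-likelihood ratio for a single window."""
    if not (0 <= c <= n <= N and c <= C <= N and C - c <= N - n):
        raise ValueError(
            f"invalid counts c={c}, n={n}, C={C}, N={N}")
    return float(bernoulli_llr_vec(c, n, C, N))


def _align_counts(counts: pd.DataFrame):
    counts = counts.sort_values("county_id").reset_index(drop=True)
    ids = counts["county_id"].to_list()
    cases = counts["cases"].to_numpy(dtype=np.int64)
    controls = counts["controls"].to_numpy(dtype=np.int64)
    if (cases < 0).any() or (controls < 0).any():
        raise ValueError("negative case/control counts")
    return ids, cases, cases + controls


def generate_windows(centroids: pd.DataFrame,
                     counts: pd.DataFrame | None = None,
                     shapes=DEFAULT_SHAPES,
                     n_angles: dict | None = None,
                     max_fraction: float = 0.25,
                     cap_on: str = "total") -> list[tuple[str, ...]]:
    """Unique candidate windows (tuples of county ids).

    For every center county, ellipse shape and orientation, counties are
    ordered by elliptic distance and nested prefix windows are emitted while
    the cap holds.  ``cap_on="total"`` (default, the scan convention) caps the
    window's observations at ``max_fraction`` of N; ``cap_on="cases"`` caps
    window cases at ``max_fraction`` of C (the literal reading).  Without
    ``counts`` no cap is applied.
    """
    if n_angles is None:
        n_angles = DEFAULT_ANGLES
    cent = centroids.sort_values("county_id").reset_index(drop=True)
    ids = cent["county_id"].to_list()
    if len(ids) < 2:
        raise WindowConfigError("need at least 2 counties to scan")
    x = cent["x_km"].to_numpy(dtype=float)
    y = cent["y_km"].to_numpy(dtype=float)

    budget = None
    weight = None
    if counts is not None:
        cids, cases, totals = _align_counts(counts)
        if cids != ids:
            raise WindowConfigError("counts and centroids county ids differ")
        weight = totals if cap_on == "total" else cases
        if cap_on not in ("total", "cases"):
            raise WindowConfigError(f"unknown cap_on={cap_on!r}")
        budget = max_fraction * weight.sum()

    id_rank = np.arange(len(ids))  # ids already sorted lexicographically
    seen: set[frozenset] = set()
    windows: list[tuple[str, ...]] = []
    for i in range(len(ids)):
        dx = x - x[i]
        dy = y - y[i]
        for s in shapes:
            for k in range(n_angles.get(s, 1)):
                theta = np.pi * k / n_angles.get(s, 1)
                u = dx * np.cos(theta) + dy * np.sin(theta)
                v = -dx * np.sin(theta) + dy * np.cos(theta)
                d2 = (u / s) ** 2 + v ** 2
                order = np.lexsort((id_rank, d2))
                acc = 0.0
                members: list[int] = []
                for j in order:
                    if budget is not None:
                        acc += weight[j]
                        if acc > budget:
                            break
                    members.append(j)
                    key = frozenset(members)
                    if key not in seen:
                        seen.add(key)
                        windows.append(tuple(sorted(ids[m] for m in members)))
    if not windows:
        raise WindowConfigError(
            "no window satisfies the size cap; every single county exceeds"
            f" {max_fraction:.0%} of the {cap_on} count")
    return windows


def cluster_rr(c: float, n: float, C: float, N: float) -> float:
    """Observed/expected relative risk of a window, inside vs outside."""
    E = n * C / N
    if E == 0:
        return np.nan
    if C - c == 0:
        return np.inf if c > 0 else np.nan
    return (c / E) / ((C - c) / (C - E))


def run_scan(counts: pd.DataFrame,
             windows: list[tuple[str, ...]],
             n_sim: int = 999,
             seed: int | None = None,
             alpha: float | None = 0.05) -> list[Cluster]:
    """Scan, rank and test candidate clusters.

    Returns non-overlapping clusters ordered by LLR; each p-value compares the
    cluster's LLR against the Monte Carlo distribution of the maximum LLR over
    all windows under case-label permutation (p = (1 + #{max >= obs}) /
    (1 + n_sim)).  With ``alpha`` set, only clusters with p < alpha are
    reported; ``alpha=None`` reports all positive-LLR non-overlapping
    clusters (the primary cluster first) regardless of significance.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    ids, cases, totals = _align_counts(counts)
    C = int(cases.sum())
    N = int(totals.sum())
    if C < 1:
        raise ValueError("no cases to scan")
    if not windows:
        return []

    pos = {cid: k for k, cid in enumerate(ids)}
    W = np.zeros((len(windows), len(ids)), dtype=np.int64)
    for w, members in enumerate(windows):
        for cid in members:
            W[w, pos[cid]] = 1
    n_in = W @ totals
    c_in = W @ cases
    llr = bernoulli_llr_vec(c_in, n_in, C, N)

    # ranked non-overlapping candidates (ties: smaller n, then member ids)
    order = sorted(range(len(windows)),
                   key=lambda w: (-llr[w], n_in[w], windows[w]))
    taken: set[str] = set()
    candidates: list[int] = []
    for w in order:
        if llr[w] <= 0:
            break
        if taken.intersection(windows[w]):
            continue
        candidates.append(w)
        taken.update(windows[w])
    if not candidates:
        return []

    rng = np.random.default_rng(seed)
    reps = rng.multivariate_hypergeometric(totals, C, size=n_sim)
    max_rep = np.empty(n_sim)
    # chunked to bound the (n_sim x n_windows) LLR matrix
    step = max(1, int(2e7) // max(1, len(windows)))
    for a in range(0, n_sim, step):
        block = reps[a:a + step] @ W.T
        max_rep[a:a + len(block)] = bernoulli_llr_vec(
            block, n_in[None, :], C, N).max(axis=1)

    clusters: list[Cluster] = []
    for rank, w in enumerate(candidates, start=1):
        p = (1 + int(np.count_nonzero(max_rep >= llr[w]))) / (1 + n_sim)
        if alpha is not None and p >= alpha:
            break  # lower-LLR clusters cannot reach significance
        clusters.append(Cluster(
            counties=windows[w], cases=int(c_in[w]), n=int(n_in[w]),
            llr=float(llr[w]), rr=float(cluster_rr(c_in[w], n_in[w], C, N)),
            p_value=p, rank=rank))
    return clusters


def prune_low_rr_counties(cluster: Cluster,
                          counts: pd.DataFrame) -> Cluster | None:
    """Drop member counties whose own single-county RR is below 1.

    Cluster cases, n and RR are recomputed on the pruned membership; the LLR
    and p-value of the original window are kept (the inference stands on the
    detected window; pruning only trims non-elevated neighbours).  Returns
    None (with a warning) if pruning empties the cluster.
    """
    ids, cases, totals = _align_counts(counts)
    pos = {cid: k for k, cid in enumerate(ids)}
    C = int(cases.sum())
    N = int(totals.sum())
    keep = []
    for cid in cluster.counties:
        k = pos[cid]
        rr = cluster_rr(cases[k], totals[k], C, N)
        if np.isfinite(rr) and rr >= 1.0 or rr == np.inf:
            keep.append(cid)
    if not keep:
        logger.warning("pruning removed every county of cluster rank %d;"
                       " cluster dropped", cluster.rank)
        return None
    idx = [pos[cid] for cid in keep]
    c = int(cases[idx].sum())
    n = int(totals[idx].sum())
    return replace(cluster, counties=tuple(keep), cases=c, n=n,
                   rr=float(cluster_rr(c, n, C, N)))


def aggregate_case_control(visits: pd.DataFrame, calendar: pd.DataFrame,
                           hazard: str, outcome: str | None = None,
                           season: tuple[int, int] = (5, 9)) -> pd.DataFrame:
    """Per-county case (event-day visit) and control tallies for one hazard.

    A visit is a case iff its county-day carries the hazard flag.  Restricted
    to the stated outcome and warm-season months; visits on county-days
    outside the calendar domain are rejected with a log message.  Every
    calendar county appears in the output (possibly with zero counts).
    """
    from .exposure import HAZARD_COLUMNS
    col = HAZARD_COLUMNS[hazard]
    v = visits
    if outcome is not None:
        v = v[v["outcome"] == outcome]
    months = pd.DatetimeIndex(v["date"]).month
    v = v[(months >= season[0]) & (months <= season[1])]
    flags = calendar.set_index(["county_id", "date"])[col]
    key = pd.MultiIndex.from_frame(v[["county_id", "date"]])
    known = key.isin(flags.index)
    if (~known).any():
        logger.warning("%d visits on county-days outside the exposure"
                       " calendar were rejected", int((~known).sum()))
    v = v[known]
    is_case = flags.loc[pd.MultiIndex.from_frame(
        v[["county_id", "date"]])].to_numpy()
    counties = sorted(calendar["county_id"].unique())
    tab = pd.DataFrame({"county_id": v["county_id"].to_numpy(),
                        "case": is_case})
    agg = tab.groupby("county_id")["case"].agg(["sum", "count"])
    out = pd.DataFrame({"county_id": counties})
    out["cases"] = out["county_id"].map(agg["sum"]).fillna(0).astype(int)
    out["controls"] = (out["county_id"].map(agg["count"]).fillna(0).astype(int)
                       - out["cases"])
    return out


def label_visits(visits: pd.DataFrame,
                 clusters: list[Cluster]) -> pd.DataFrame:
    """Add a ``high_risk`` flag: visit county belongs to a reported cluster."""
    high = set()
    for cl in clusters:
        high.update(cl.counties)
    out = visits.copy()
    out["high_risk"] = out["county_id"].isin(high)
    return out


def clusters_to_frame(clusters: list[Cluster]) -> pd.DataFrame:
    """Table-2-shaped summary: one row per cluster."""
    rows = [{
        "rank": cl.rank, "county_ids": ";".join(cl.counties),
        "n_counties": len(cl.counties), "cases": cl.cases, "n": cl.n,
        "llr": cl.llr, "rr": cl.rr, "p_value": cl.p_value,
    } for cl in clusters]
    return pd.DataFrame(rows, columns=["rank", "county_ids", "n_counties",
                                       "cases", "n", "llr", "rr", "p_value"])
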