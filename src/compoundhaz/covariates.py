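"""County covariate assembly: segregation indices and the predictor roster.

The Index of Concentration at the Extremes (ICE) summarises how concentrated
a county's population is at the advantaged versus deprived pole of a social
axis: ICE = (A - P) / T with A advantaged persons, P deprived persons and T
total population, so ICE = 1 when everyone is in the privileged group and
-1 when everyone is in the deprived group.  Three variants are carried
(racial, economic, racialized-economic); one of them, configurable, enters
the models as ``residential_segregation``.

The remaining roster mirrors Community Resilience Estimate style household
and community variables (proportions in [0, 1], a housing-unit count, and
greenspace per person in m^2/person derived from green area and population).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

ICE_VARIANTS = ("racial", "economic", "racialized_economic")

#: proportion-valued roster columns (must lie in [0, 1])
PROPORTION_COLUMNS = (
    "pct_age_65_plus",
    "pct_hs_grad_or_higher",
    "pct_no_vehicle",
    "pct_overcrowded",
    "pct_low_english",
    "pct_no_health_coverage",
    "pct_broadband",
    "homeowner_vacancy_rate",
    "rental_vacancy_rate",
    "pct_veterans",
    "pct_hispanic",
)

#: full predictor roster, in model-entry order
COVARIATE_ROSTER = PROPORTION_COLUMNS + (
    "housing_units",
    "residential_segregation",
    "greenspace_per_person",
)


class JoinError(ValueError):
    """A county is missing from one of the covariate sources."""


def compute_ice(advantaged, deprived, total):
    """(A - P) / T, elementwise; validates A, P >= 0, A + P <= T, T > 0."""
    a = np.asarray(advantaged, dtype=float)
    p = np.asarray(deprived, dtype=float)
    t = np.asarray(total, dtype=float)
    if (t <= 0).any():
        raise ValueError("total population must be positive")
    if (a < 0).any() or (p < 0).any():
        raise ValueError("group counts must be non-negative")
    if (a + p > t + 1e-9).any():
        raise ValueError("advantaged + deprived exceeds total")
    out = (a - p) / t
    return float(out) if out.ndim == 0 else out


def _check_counties(frames: dict[str, pd.DataFrame], counties) -> None:
    want = set(counties)
    for name, f in frames.items():
        missing = want - set(f["county_id"])
        if missing:
            raise JoinError(f"{name} is missing counties: {sorted(missing)}")


def assemble_covariates(props: pd.DataFrame,
                        greenspace: pd.DataFrame,
                        ice_counts: pd.DataFrame,
                        ice_variant: str = "racialized_economic",
                        ) -> pd.DataFrame:
    """Join, validate and bound the county covariate table.

    ``props``: county_id plus the proportion columns and ``housing_units``.
    ``greenspace``: county_id, green_area_km2, population.
    ``ice_counts``: county_id, variant, advantaged, deprived, total (one row
    per county per ICE variant).  Greenspace per person is reported in
    m^2/person.  The chosen ICE variant is copied into
    ``residential_segregation``; all three variants are kept as ice_* columns.
    """
    if ice_variant not in ICE_VARIANTS:
        raise ValueError(f"unknown ICE variant {ice_variant!r}")
    counties = sorted(props["county_id"])
    _check_counties({"greenspace": greenspace, "ice_counts": ice_counts},
                    counties)
    out = props.set_index("county_id").sort_index().copy()
    for col in PROPORTION_COLUMNS:
        bad = out[(out[col] < 0) | (out[col] > 1)]
        if not bad.empty:
            raise ValueError(
                f"column {col} outside [0, 1] for counties"
                f" {bad.index.tolist()}")
    if (out["housing_units"] < 0).any():
        raise ValueError("housing_units must be non-negative")

    gs = greenspace.set_index("county_id").loc[counties]
    if (gs["green_area_km2"] < 0).any():
        raise ValueError("green area must be non-negative")
    out["greenspace_per_person"] = (gs["green_area_km2"] * 1e6
                                    / gs["population"])

    for variant in ICE_VARIANTS:
        sub = ice_counts[ice_counts["variant"] == variant]
        if sub.empty:
            continue
        _check_counties({f"ice_counts[{variant}]": sub}, counties)
        sub = sub.set_index("county_id").loc[counties]
        out[f"ice_{variant}"] = compute_ice(
            sub["advantaged"], sub["deprived"], sub["total"])
    seg_col = f"ice_{ice_variant}"
    if seg_col not in out.columns:
        raise JoinError(f"ice_counts has no rows for variant {ice_variant!r}")
    out["residential_segregation"] = out[seg_col]
    return out.reset_index()


def write_covariates_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_covariates_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
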