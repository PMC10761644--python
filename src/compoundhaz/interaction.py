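"""Additive and multiplicative interaction of two exposures from three RRs.

Given the relative risks for heatwave alone (RR10), drought alone (RR01) and
the compound exposure (RR11), all against the doubly-unexposed reference:

* RERI = RR11 - RR10 - RR01 + 1           (0 under exact additivity)
* Synergy index S = (RR11 - 1) / ((RR10 - 1) + (RR01 - 1))   (1 if additive)
* Multiplicative ratio = RR11 / (RR10 * RR01)                (1 if
  multiplicative)

RERI < 0 and S < 1 indicate less-than-additive joint effects; a ratio < 1
indicates negative multiplicative interaction.  S is undefined (flagged, not
a number) when (RR10 - 1) + (RR01 - 1) = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class RiskTriple:
    """The three relative risks entering the interaction measures."""

    rr10: float  #: heatwave alone
    rr01: float  #: drought alone
    rr11: float  #: compound exposure

    def __post_init__(self):
        for name in ("rr10", "rr01", "rr11"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and positive, got {v}")


@dataclass(frozen=True)
class InteractionMeasures:
    reri: float
    synergy: float  #: NaN when undefined
    synergy_defined: bool
    multiplicative: float
    additive_direction: str
    multiplicative_direction: str


def reri(t: RiskTriple) -> float:
    """Relative excess risk due to interaction."""
    return t.rr11 - t.rr10 - t.rr01 + 1.0


def synergy_index(t: RiskTriple) -> float:
    """Rothman synergy index; NaN when the denominator is exactly zero."""
    denom = (t.rr10 - 1.0) + (t.rr01 - 1.0)
    if denom == 0.0:
        return math.nan
    return (t.rr11 - 1.0) / denom


def multiplicative_ratio(t: RiskTriple) -> float:
    return t.rr11 / (t.rr10 * t.rr01)


def _direction(value: float, neutral: float) -> str:
    if value < neutral:
        return "less than additivity"
    if value > neutral:
        return "greater than additivity"
    return "exactly additive"


def interaction_measures(t: RiskTriple) -> InteractionMeasures:
    """All three measures with qualitative direction flags."""
    r = reri(t)
    s = synergy_index(t)
    m = multiplicative_ratio(t)
    mult_dir = ("negative multiplicative interaction" if m < 1
                else "positive multiplicative interaction" if m > 1
                else "exactly multiplicative")
    return InteractionMeasures(
        reri=r, synergy=s, synergy_defined=not math.isnan(s),
        multiplicative=m, additive_direction=_direction(r, 0.0),
        multiplicative_direction=mult_dir)


def measures_record(t: RiskTriple, decimals: int = 2) -> dict:
    """JSON-ready record, values rounded for reporting."""
    m = interaction_measures(t)
    return {
        "rr10": t.rr10, "rr01": t.rr01, "rr11": t.rr11,
        "reri": round(m.reri, decimals),
        "synergy": None if not m.synergy_defined else round(m.synergy,
                                                            decimals),
        "synergy_defined": m.synergy_defined,
        "multiplicative_ratio": round(m.multiplicative, decimals),
        "additive_direction": m.additive_direction,
        "multiplicative_direction": m.multiplicative_direction,
    }
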