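"""Quartile-based decision-support instrument grading municipality snakebite risk.

The instrument classifies each municipality into one of four risk levels by
combining two pieces of information:

* **Epidemiological class** (High/Low), from *within-state* quartiles of case
  counts and incidence rates, plus any recorded death.  A municipality is
  epidemiologically High when it sits in the top state quartile of cases OR
  of rates OR recorded at least one death (OR is the sensitive choice for a
  decision-support tool; both knobs are configurable).
* **Driver count** d_i, from *national* quartiles of the model-selected
  environmental/socioeconomic drivers.  For risk-increasing drivers
  (tropical habitat, temperature, precipitation, elevation, snake richness,
  forest loss) the high-risk quartile is the top one (>= q3); for protective
  drivers (urbanisation, GDP per capita — rate ratios below 1 in the count
  model) it is the bottom one (<= q1).  The tropical dichotomy counts 1 when
  tropical.  d_i >= 4 means "many" drivers.

The final grade is a configurable 2x2 combination table, default:

    (High, many) -> High        (High, few) -> MediumHigh
    (Low,  many) -> MediumLow   (Low,  few) -> Low

Forest cover is deliberately not an instrument driver (its association with
counts is borderline), leaving 8 candidate drivers.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .surveillance import incidence_rate

__all__ = [
    "DEFAULT_DIRECTIONS",
    "DEFAULT_COMBINATION",
    "INSTRUMENT_DRIVERS",
    "QuartileCutoffs",
    "quartile_cutoffs",
    "epi_class",
    "count_high_risk_drivers",
    "stratify",
    "grade_municipalities",
]

RISK_INCREASING = "risk_increasing"
RISK_DECREASING = "risk_decreasing"

#: direction of risk for each instrument driver (forest cover excluded)
DEFAULT_DIRECTIONS: dict[str, str] = {
    "habitat_tropical": RISK_INCREASING,
    "temperature": RISK_INCREASING,
    "precipitation": RISK_INCREASING,
    "elevation": RISK_INCREASING,
    "snake_richness": RISK_INCREASING,
    "forest_loss": RISK_INCREASING,
    "urban_pct": RISK_DECREASING,
    "gdp_per_capita": RISK_DECREASING,
}

INSTRUMENT_DRIVERS = tuple(DEFAULT_DIRECTIONS)

DEFAULT_COMBINATION: dict[tuple[str, bool], str] = {
    ("High", True): "High",
    ("High", False): "MediumHigh",
    ("Low", True): "MediumLow",
    ("Low", False): "Low",
}

GRADES = ("High", "MediumHigh", "MediumLow", "Low")
MANY_THRESHOLD = 4


@dataclass(frozen=True)
class QuartileCutoffs:
    """Quartile cutoffs for one variable at state or national scope."""

    variable: str
    scope: str                     # "state" | "national"
    q1: float
    q2: float
    q3: float
    direction: str                 # risk_increasing | risk_decreasing
    dichotomous: bool = False

    def __post_init__(self):
        if not self.q1 <= self.q2 <= self.q3:
            raise ValueError(f"{self.variable}: quartiles must be ascending")
        if self.direction not in (RISK_INCREASING, RISK_DECREASING):
            raise ValueError(f"{self.variable}: direction must be declared")


def quartile_cutoffs(
    values: Sequence[float],
    variable: str,
    scope: str,
    direction: str,
    dichotomous: bool = False,
) -> QuartileCutoffs:
    """25th/50th/75th percentiles (linear interpolation) of the values."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) < 4:
        raise ValueError(f"{variable}: need at least 4 non-missing values for quartiles")
    q1, q2, q3 = np.percentile(v, [25, 50, 75])
    return QuartileCutoffs(variable, scope, float(q1), float(q2), float(q3),
                           direction, dichotomous)


def epi_class(
    cases: float,
    rate: float,
    any_deaths: bool,
    cases_cutoffs: QuartileCutoffs,
    rate_cutoffs: QuartileCutoffs,
    deaths_force_high: bool = True,
) -> str:
    """High/Low epidemiological class from within-state quartiles and deaths.

    High when cases >= state q3 of cases, OR rate >= state q3 of rates, OR
    (if ``deaths_force_high``) any death was recorded.  A death without a
    recorded case is honoured but flagged by the caller as a data-quality
    issue.
    """
    if cases_cutoffs is None or rate_cutoffs is None:
        raise ValueError("state-level cutoffs required for both cases and rate")
    high = cases >= cases_cutoffs.q3 or rate >= rate_cutoffs.q3
    if deaths_force_high and any_deaths:
        high = True
    return "High" if high else "Low"


def count_high_risk_drivers(
    driver_values: Mapping[str, float],
    cutoffs: Mapping[str, QuartileCutoffs],
) -> int:
    """Number of drivers in their national high-risk quartile, d_i.

    Risk-increasing drivers count when >= q3; protective (risk-decreasing)
    drivers count when <= q1; a dichotomous driver counts when equal to 1.
    Every driver must carry declared cutoffs with a direction — there is no
    silent default.
    """
    d = 0
    for name, value in driver_values.items():
        if name not in cutoffs:
            raise KeyError(f"no quartile cutoffs declared for driver {name!r}")
        c = cutoffs[name]
        if c.dichotomous:
            d += int(value == 1)
        elif c.direction == RISK_INCREASING:
            d += int(value >= c.q3)
        else:
            d += int(value <= c.q1)
    return d


def stratify(
    epi: str,
    many_drivers: bool,
    combination: Mapping[tuple[str, bool], str] = DEFAULT_COMBINATION,
) -> str:
    """Final four-level grade from the 2x2 combination table."""
    if epi not in ("High", "Low"):
        raise ValueError(f"unresolved epidemiological class {epi!r}")
    key = (epi, bool(many_drivers))
    if key not in combination:
        raise ValueError(f"combination table lacks entry for {key!r}")
    return combination[key]


def grade_municipalities(
    surveillance: pd.DataFrame,
    drivers: pd.DataFrame,
    years: float = 5.0,
    directions: Mapping[str, str] = DEFAULT_DIRECTIONS,
    many_threshold: int = MANY_THRESHOLD,
    combination: Mapping[tuple[str, bool], str] = DEFAULT_COMBINATION,
    deaths_force_high: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Grade every municipality; returns (grades table, cutoffs snapshot).

    ``surveillance`` needs columns ``muni_id, state_id, population, cases,
    deaths``; ``drivers`` needs ``muni_id`` plus the configured driver
    columns.  Epidemiological quartiles are computed within each state,
    driver quartiles nationally.  The cutoffs snapshot is serialisable and
    emitted alongside results for auditability.
    """
    df = surveillance.merge(drivers, on="muni_id", validate="one_to_one")
    if df.empty:
        raise ValueError("no municipalities after joining surveillance and drivers")
    df = df.copy()
    df["rate"] = [
        incidence_rate(c, years, p) for c, p in zip(df["cases"], df["population"])
    ]

    state_cut: dict[str, dict[str, QuartileCutoffs]] = {}
    for sid, g in df.groupby("state_id"):
        state_cut[sid] = {
            "cases": quartile_cutoffs(g["cases"], "cases", "state", RISK_INCREASING),
            "rate": quartile_cutoffs(g["rate"], "rate", "state", RISK_INCREASING),
        }

    national_cut: dict[str, QuartileCutoffs] = {}
    for name, direction in directions.items():
        if name not in df.columns:
            raise KeyError(f"driver column {name!r} missing from drivers table")
        national_cut[name] = quartile_cutoffs(
            df[name], name, "national", direction,
            dichotomous=set(df[name].dropna().unique()) <= {0, 1},
        )

    rows = []
    for _, row in df.iterrows():
        cuts = state_cut[row["state_id"]]
        epi = epi_class(
            row["cases"], row["rate"], row["deaths"] > 0,
            cuts["cases"], cuts["rate"], deaths_force_high=deaths_force_high,
        )
        d_i = count_high_risk_drivers(
            {name: row[name] for name in directions}, national_cut
        )
        many = d_i >= many_threshold
        rows.append(
            {
                "muni_id": row["muni_id"],
                "state_id": row["state_id"],
                "epi_class": epi,
                "any_deaths": bool(row["deaths"] > 0),
                "death_without_case": bool(row["deaths"] > 0 and row["cases"] == 0),
                "driver_count": d_i,
                "many_drivers": many,
                "grade": stratify(epi, many, combination),
            }
        )
    grades = pd.DataFrame(rows)

    snapshot = {
        "many_threshold": many_threshold,
        "deaths_force_high": deaths_force_high,
        "combination": {f"{k[0]}|{'many' if k[1] else 'few'}": v for k, v in combination.items()},
        "national": {k: asdict(v) for k, v in national_cut.items()},
        "state": {s: {k: asdict(v) for k, v in cc.items()} for s, cc in state_cut.items()},
    }
    return grades, snapshot
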