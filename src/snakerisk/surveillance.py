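"""Descriptive surveillance statistics for municipality-level snakebite data.

Implements the quantities tabulated in state-level surveillance summaries:
annual case averages, annualised incidence per 100,000 population,
case-fatality percentages, aggregation of municipality records to state /
region / country, case shares, and Fisher-Jenks natural-breaks
classification for thematic (choropleth) mapping.

Rounding is half-up to two decimals throughout, matching how surveillance
tables are printed (banker's rounding would flip e.g. 0.625 -> 0.62).
A municipality with zero cases has an undefined case-fatality rate; it is
reported as missing, never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "round_half_up",
    "annual_average",
    "incidence_rate",
    "fatality_rate",
    "share_of_total",
    "mean_per_unit",
    "RateSummary",
    "aggregate",
    "jenks_breaks",
    "jenks_classify",
    "load_reference_table",
]

LEVELS = ("state", "region", "country")


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero at the given decimal place."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def annual_average(total: float, years: float) -> int:
    """Average events per year over the reporting window, rounded half-up."""
    if years <= 0:
        raise ValueError("years must be positive")
    if total < 0:
        raise ValueError("total must be non-negative")
    return int(round_half_up(total / years))


def incidence_rate(cases_total: float, years: float, population: float) -> float:
    """Annualised incidence per 100,000 population, 2 decimals half-up."""
    if population <= 0:
        raise ValueError("population must be positive")
    if years <= 0:
        raise ValueError("years must be positive")
    return round_half_up(cases_total / years / population * 1e5, 2)


def fatality_rate(deaths: float, cases: float) -> float:
    """Case-fatality percentage, 2 decimals half-up; NaN when no cases."""
    if deaths < 0:
        raise ValueError("deaths must be non-negative")
    if cases == 0:
        return float("nan")  # undefined, reported as missing
    if deaths > cases:
        raise ValueError("deaths cannot exceed cases")
    return round_half_up(deaths / cases * 100.0, 2)


def share_of_total(part: float, total: float) -> float:
    """Percentage share, 2 decimals half-up."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= part <= total:
        raise ValueError("part must lie in [0, total]")
    return round_half_up(part / total * 100.0, 2)


def mean_per_unit(total: float, n_units: int) -> float:
    """Mean events per unit, 2 decimals half-up."""
    if n_units <= 0:
        raise ValueError("n_units must be positive")
    return round_half_up(total / n_units, 2)


@dataclass
class RateSummary:
    """One row of a surveillance summary table for an aggregation unit."""

    unit_id: str
    population: int
    cases_total: int
    cases_annual_avg: int
    rate_per_100k: float
    deaths_total: int
    deaths_annual_avg: int
    fatality_pct: float

    @classmethod
    def from_counts(
        cls, unit_id: str, population: int, cases: int, deaths: int, years: float
    ) -> "RateSummary":
        return cls(
            unit_id=unit_id,
            population=int(population),
            cases_total=int(cases),
            cases_annual_avg=annual_average(cases, years),
            rate_per_100k=incidence_rate(cases, years, population),
            deaths_total=int(deaths),
            deaths_annual_avg=annual_average(deaths, years),
            fatality_pct=fatality_rate(deaths, cases),
        )


def aggregate(records, level: str = "state", years: float | None = None) -> pd.DataFrame:
    """Aggregate municipality records to state, region or country summaries.

    ``records`` may be a list of :class:`~snakerisk.synthetic.MunicipalityRecord`
    or a DataFrame with columns ``state_id, region_id, population, cases,
    deaths`` (and optionally ``years``).  Counts and population are summed
    within each group before the rate formulas are applied, so aggregation is
    associative: municipality->state->country equals municipality->country.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    if not isinstance(records, pd.DataFrame):
        from .synthetic import records_to_frames

        records, _ = records_to_frames(records)
    if records.empty:
        return pd.DataFrame(
            columns=[
                "unit_id", "population", "cases_total", "cases_annual_avg",
                "rate_per_100k", "deaths_total", "deaths_annual_avg", "fatality_pct",
            ]
        )
    if years is None:
        years = float(records["years"].iloc[0]) if "years" in records else 5.0
    key = {"state": "state_id", "region": "region_id", "country": None}[level]
    df = records.copy()
    if key is None:
        df["_group"] = "country"
        key = "_group"
    grouped = df.groupby(key, sort=True).agg(
        population=("population", "sum"), cases=("cases", "sum"), deaths=("deaths", "sum")
    )
    rows = [
        RateSummary.from_counts(str(unit), int(g.population), int(g.cases), int(g.deaths), years)
        for unit, g in grouped.iterrows()
    ]
    return pd.DataFrame([vars(r) for r in rows])


# ---------------------------------------------------------------------- #
# Fisher-Jenks natural breaks
# ---------------------------------------------------------------------- #
def jenks_breaks(values: Sequence[float], k: int) -> list[float]:
    """Optimal natural-breaks class bounds minimising within-class SSD.

    Returns the ``k-1`` ascending break points, each the upper bound (maximum
    member) of one of the first ``k-1`` classes; values <= break fall in the
    class below.  The partition is the exact optimum of the Fisher-Jenks
    dynamic programme over contiguous classes of the sorted data.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if k < 2:
        raise ValueError("need at least 2 classes")
    if len(np.unique(x)) < k:
        raise ValueError("need at least k distinct values")

    # prefix sums for O(1) within-class SSD of x[i:j]
    cs = np.concatenate(([0.0], np.cumsum(x)))
    cs2 = np.concatenate(([0.0], np.cumsum(x**2)))

    def ssd(i: int, j: int) -> float:  # cost of class x[i:j], j exclusive
        s, s2, m = cs[j] - cs[i], cs2[j] - cs2[i], j - i
        return s2 - s * s / m

    INF = float("inf")
    # cost[c][j]: optimal SSD of splitting x[:j] into c+1 classes
    cost = np.full((k, n + 1), INF)
    back = np.zeros((k, n + 1), dtype=int)
    for j in range(1, n + 1):
        cost[0][j] = ssd(0, j)
    for c in range(1, k):
        for j in range(c + 1, n + 1):
            i = np.arange(c, j)
            tail = (cs2[j] - cs2[i]) - (cs[j] - cs[i]) ** 2 / (j - i)
            cand = cost[c - 1][i] + tail
            arg = int(np.argmin(cand))
            cost[c][j], back[c][j] = cand[arg], i[arg]
    # recover class boundaries (indices where a new class starts)
    cuts = []
    j = n
    for c in range(k - 1, 0, -1):
        i = back[c][j]
        cuts.append(i)
        j = i
    cuts.reverse()
    return [float(x[i - 1]) for i in cuts]


def jenks_classify(values: Sequence[float], breaks: Sequence[float]) -> np.ndarray:
    """Assign each value a class index 0..k-1 given ascending upper-bound breaks."""
    return np.searchsorted(np.asarray(breaks, dtype=float), np.asarray(values, dtype=float), side="left")


def load_reference_table() -> pd.DataFrame:
    """The published Brazilian state-level snakebite table, 2013-2017.

    Columns: ``unit_id, level, region, population, cases, deaths`` with one
    row per state, per region, and the country total, as printed in the
    source surveillance table.  Derived statistics (annual averages, rates,
    case-fatality) are recomputed by this package, not stored.
    """
    from importlib.resources import files

    path = files("snakerisk.data").joinpath("brazil_snakebite_2013_2017.csv")
    with path.open("rb") as fh:
        return pd.read_csv(fh)
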