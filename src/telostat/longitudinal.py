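"""Repeated-measurement comparison: rates of TL/TLS change over time.

For an individual sampled on several dates, consecutive pairwise rates of
change of the summary statistic (the median by default) are computed as
Δvalue / Δyears (years = days / 365.25).  With three or more points an
overall least-squares slope is also reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Sequence

import numpy as np

from telostat.data_model import chronological_age
from telostat.descriptive_stats import DescriptiveSummary
from telostat.errors import DomainError

DAYS_PER_YEAR = 365.25


@dataclass
class LongitudinalSeries:
    """An individual's repeated TL summaries and between-visit rates."""

    sample_base_code: str
    points: list[tuple[date, DescriptiveSummary, int]]  # (date, summary, repeat)
    rates: list[tuple[float, float, float]]  # (interval_years, delta_bases, rate)
    overall_slope_bases_per_year: float | None = None


def rate_of_change(
    series: Sequence[tuple[date, float]],
) -> list[tuple[float, float]]:
    """Consecutive pairwise rates (interval_years, rate_bases_per_year).

    Requires ≥2 points with strictly increasing dates.
    """
    if len(series) < 2:
        raise DomainError("rate of change needs at least two measurements")
    dates = [d for d, _ in series]
    if any(b <= a for a, b in zip(dates, dates[1:])):
        raise DomainError("measurement dates must be strictly increasing")
    rates = []
    for (d0, v0), (d1, v1) in zip(series, series[1:]):
        dt = chronological_age(d0, d1)
        rates.append((dt, (v1 - v0) / dt))
    return rates


def overall_slope(series: Sequence[tuple[date, float]]) -> float:
    """Least-squares slope (bases/year) across all points."""
    if len(series) < 2:
        raise DomainError("overall slope needs at least two measurements")
    t0 = series[0][0]
    x = np.array([(d - t0).days / DAYS_PER_YEAR for d, _ in series])
    y = np.array([v for _, v in series])
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)


def build_series(
    sample_base_code: str,
    points: Sequence[tuple[date, DescriptiveSummary, int]],
    statistic: str = "median",
) -> LongitudinalSeries:
    """Assemble a longitudinal series and its rates from repeat summaries.

    ``statistic`` selects which summary field the rate is computed on
    (``median`` by default; any numeric DescriptiveSummary field works).
    """
    pts = sorted(points, key=lambda p: p[0])
    repeats = [r for _, _, r in pts]
    if any(b <= a for a, b in zip(repeats, repeats[1:])):
        raise DomainError("repeat_index must increase with sampling date")
    values = [(d, float(getattr(s, statistic))) for d, s, _ in pts]
    pair_rates = rate_of_change(values)
    rates = [
        (dt, (values[i + 1][1] - values[i][1]), r)
        for i, (dt, r) in enumerate(pair_rates)
    ]
    slope = overall_slope(values) if len(values) >= 3 else None
    return LongitudinalSeries(sample_base_code, pts, rates, slope)
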