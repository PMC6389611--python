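"""Population TL-vs-age reference curves and biological-age estimation.

A nomogram is a family of percentile curves of telomere length against
chronological age: individuals are binned into age groups (decadal by
default), the pooled TL values of each group are reduced to a set of
percentile levels (TL10 … TL95), and each level is fitted with an ordinary
least-squares line against the age-group midpoint.  Because mean TL declines
roughly linearly with adult age, the fitted lines slope downward and can be
inverted:

    biological_age = (median_TL − a) / b

where (a, b) are the intercept and slope of the percentile curve nearest
(by vertical distance) to the individual's median TL at their chronological
age.  An individual whose median lies below the population median curve is
flagged as biologically older than their calendar age; the estimate carries
a warning when the nearest-line inversion contradicts that expectation,
which can happen near curve crossovers.

The same construction applies to short-telomere (TLS) profiles; the source
is recorded on the nomogram.
"""

from __future__ import annotations

import json
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from telostat.data_model import IndividualRecord
from telostat.descriptive_stats import (
    DescriptiveSummary,
    TLProfile,
    descriptive_summary,
    detect_short_telomeres,
    percentile_linear,
)
from telostat.errors import ConfigError, DomainError, EstimationError

DEFAULT_PERCENTILE_LEVELS: tuple[int, ...] = (10, 25, 50, 75, 90, 95)
#: Decadal age bins 20–89; the last edge is exclusive.
DEFAULT_AGE_EDGES: tuple[float, ...] = (20, 30, 40, 50, 60, 70, 80, 90)

AGE_CLAMP_MARGIN_YEARS = 10.0


@dataclass(frozen=True)
class LinearFit:
    """OLS line value = intercept + slope·age for one percentile level."""

    intercept: float
    slope: float
    r_squared: float
    degenerate: bool = False  # zero-variance fit; r_squared reported as 1


@dataclass
class Nomogram:
    """Percentile reference curves of TL (or TLS) against age."""

    source: str  # "TL" or "TLS"
    age_group_edges: np.ndarray
    age_group_midpoints: np.ndarray
    percentile_levels: tuple[int, ...]
    curve_values: np.ndarray  # [n_groups, n_levels], bases
    fit_per_level: dict[int, LinearFit]
    group_counts: list[int] = field(default_factory=list)

    @property
    def age_min(self) -> float:
        return float(self.age_group_edges[0])

    @property
    def age_max(self) -> float:
        return float(self.age_group_edges[-1])

    def curve_at(self, level: int, age: float) -> float:
        """Curve value at an age, linearly interpolated between midpoints
        (clamped outside the midpoint range)."""
        j = self.percentile_levels.index(level)
        return float(
            np.interp(age, self.age_group_midpoints, self.curve_values[:, j])
        )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "source": self.source,
            "units": {"curve_values": "bases", "age": "years"},
            "age_group_edges": list(map(float, self.age_group_edges)),
            "age_group_midpoints": list(map(float, self.age_group_midpoints)),
            "percentile_levels": list(self.percentile_levels),
            "curve_values": self.curve_values.tolist(),
            "group_counts": self.group_counts,
            "fit_per_level": {
                str(lvl): {
                    "intercept": f.intercept,
                    "slope": f.slope,
                    "r_squared": f.r_squared,
                    "degenerate": f.degenerate,
                }
                for lvl, f in self.fit_per_level.items()
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "Nomogram":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            source=d["source"],
            age_group_edges=np.asarray(d["age_group_edges"], dtype=float),
            age_group_midpoints=np.asarray(d["age_group_midpoints"], dtype=float),
            percentile_levels=tuple(d["percentile_levels"]),
            curve_values=np.asarray(d["curve_values"], dtype=float),
            fit_per_level={
                int(lvl): LinearFit(
                    f["intercept"], f["slope"], f["r_squared"], f.get("degenerate", False)
                )
                for lvl, f in d["fit_per_level"].items()
            },
            group_counts=list(d.get("group_counts", [])),
        )


@dataclass
class BioAgeEstimate:
    """Point estimate of biological age from the nearest reference line."""

    chronological_age: float
    biological_age: float
    nearest_level: int
    above_median: bool
    median_tl: float
    fit_used: LinearFit
    clamped: bool = False
    hypothesis_warning: bool = False  # inversion contradicts the above/below-median rule


def _ols_line(x: np.ndarray, y: np.ndarray) -> LinearFit:
    """Least-squares line with R²; zero-variance y reported as a flat
    perfect fit (degenerate flag set) so flat synthetic data stays usable."""
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return LinearFit(float(y[0]), 0.0, 1.0, degenerate=True)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return LinearFit(float(intercept), float(slope), r2)


def build_nomogram(
    population: Sequence[tuple[TLProfile, float]],
    source: str = "TL",
    levels: Iterable[int] = DEFAULT_PERCENTILE_LEVELS,
    age_edges: Sequence[float] = DEFAULT_AGE_EDGES,
) -> Nomogram:
    """Build percentile reference curves from a population.

    ``population`` pairs each TL profile with a chronological age in years.
    With ``source="TLS"`` each profile is first reduced to its short-telomere
    subset.  For every age group the pooled values of its members are reduced
    to the requested percentile levels with the linear engine, and each level
    is fitted with an OLS line against the group midpoint.

    Raises a build error when fewer than two age groups are occupied or when
    an occupied-range group is empty.
    """
    levels = tuple(sorted(levels))
    edges = np.asarray(age_edges, dtype=float)
    if edges.size < 3:
        raise ConfigError("need at least 2 age groups (3 edges)")
    if np.any(np.diff(edges) <= 0):
        raise ConfigError("age_edges must be strictly increasing")
    if source not in ("TL", "TLS"):
        raise ConfigError(f"source must be 'TL' or 'TLS', got {source!r}")

    n_groups = edges.size - 1
    pooled: list[list[float]] = [[] for _ in range(n_groups)]
    for profile, age in population:
        if not edges[0] <= age < edges[-1]:
            raise DomainError(
                f"age {age} outside the nomogram range [{edges[0]}, {edges[-1]})"
            )
        if source == "TLS":
            profile = detect_short_telomeres(profile)
        g = bisect_right(edges, age) - 1
        pooled[g].extend(profile.tl_bases.tolist())

    occupied = [g for g in range(n_groups) if pooled[g]]
    if len(occupied) < 2:
        raise DomainError(
            f"nomogram needs ≥2 occupied age groups, got {len(occupied)}"
        )
    empty_inside = [
        g for g in range(occupied[0], occupied[-1] + 1) if not pooled[g]
    ]
    if empty_inside:
        labels = [f"{edges[g]:.0f}–{edges[g + 1]:.0f}" for g in empty_inside]
        raise DomainError(f"empty age group(s) inside the cohort range: {labels}")

    keep = occupied
    midpoints = np.array([(edges[g] + edges[g + 1]) / 2 for g in keep])
    curve = np.array(
        [[percentile_linear(pooled[g], lvl) for lvl in levels] for g in keep]
    )
    fits = {
        lvl: _ols_line(midpoints, curve[:, j]) for j, lvl in enumerate(levels)
    }
    kept_edges = np.append(edges[keep], edges[keep[-1] + 1])
    return Nomogram(
        source=source,
        age_group_edges=kept_edges,
        age_group_midpoints=midpoints,
        percentile_levels=levels,
        curve_values=curve,
        fit_per_level=fits,
        group_counts=[len(pooled[g]) for g in keep],
    )


def estimate_biological_age(
    nomogram: Nomogram,
    median_value: float,
    chronological_age: float,
) -> BioAgeEstimate:
    """Invert the nearest percentile curve to estimate biological age.

    Steps: (1) compare the individual's median TL with the interpolated
    median (P50) curve at their chronological age; (2) pick the percentile
    curve with the smallest vertical distance at that age, ties toward the
    lower level; (3) invert that curve's OLS line,
    ``bio_age = (median_value − a)/b``; (4) clamp to the nomogram age range
    ±10 years and flag the estimate when the result contradicts the
    below-median → biologically-older expectation.
    """
    if median_value <= 0:
        raise DomainError(f"median TL must be positive, got {median_value}")
    age = float(np.clip(chronological_age, nomogram.age_min, nomogram.age_max))

    if 50 in nomogram.percentile_levels:
        median_curve = nomogram.curve_at(50, age)
    else:  # fall back to the central level
        mid_level = nomogram.percentile_levels[len(nomogram.percentile_levels) // 2]
        median_curve = nomogram.curve_at(mid_level, age)
    above_median = median_value > median_curve

    distances = [
        abs(median_value - nomogram.curve_at(lvl, age))
        for lvl in nomogram.percentile_levels
    ]
    nearest_level = nomogram.percentile_levels[int(np.argmin(distances))]
    fit = nomogram.fit_per_level[nearest_level]
    if fit.slope >= 0:
        raise EstimationError(
            f"non-decreasing reference line at level {nearest_level} "
            "(slope ≥ 0); biological age inversion is undefined"
        )
    bio_age = (median_value - fit.intercept) / fit.slope
    lo = nomogram.age_min - AGE_CLAMP_MARGIN_YEARS
    hi = nomogram.age_max + AGE_CLAMP_MARGIN_YEARS
    clamped = not (lo <= bio_age <= hi)
    bio_age = float(np.clip(bio_age, lo, hi))

    # Below the median curve should mean biologically older (and vice versa);
    # the nearest-line inversion can disagree near crossovers.
    warning = (not above_median and bio_age < chronological_age) or (
        above_median and bio_age > chronological_age
    )
    return BioAgeEstimate(
        chronological_age=float(chronological_age),
        biological_age=bio_age,
        nearest_level=nearest_level,
        above_median=above_median,
        median_tl=float(median_value),
        fit_used=fit,
        clamped=clamped,
        hypothesis_warning=warning,
    )


def group_summary(
    population: Sequence[tuple[TLProfile, IndividualRecord]],
    by: str = "age_group",
    age_edges: Sequence[float] = DEFAULT_AGE_EDGES,
    source: str = "TL",
) -> dict[str, tuple[int, DescriptiveSummary]]:
    """Pivot-style group summaries of pooled TL values.

    ``by`` is one of ``age_group``, ``sex`` or ``exposure``.  Returns an
    ordered mapping group label → (number of individuals, descriptive summary
    of the pooled values).  Groups with no members are omitted.
    """
    if by not in ("age_group", "sex", "exposure"):
        raise ConfigError(f"unknown grouping key {by!r}")
    edges = np.asarray(age_edges, dtype=float)
    groups: dict[str, list[np.ndarray]] = {}
    counts: dict[str, int] = {}

    def add(label: str, values: np.ndarray) -> None:
        groups.setdefault(label, []).append(values)
        counts[label] = counts.get(label, 0) + 1

    for profile, record in population:
        if source == "TLS":
            profile = detect_short_telomeres(profile)
        if by == "sex":
            add(record.sex, profile.tl_bases)
        elif by == "exposure":
            flags = record.exposure_flags or frozenset({"none"})
            for flag in flags:
                add(flag, profile.tl_bases)
        else:
            age = record.age_at_sampling
            g = bisect_right(edges, age) - 1
            if not 0 <= g < edges.size - 1:
                raise DomainError(f"age {age:.1f} outside the age-group edges")
            add(f"{edges[g]:.0f}–{edges[g + 1]:.0f}", profile.tl_bases)

    result: dict[str, tuple[int, DescriptiveSummary]] = {}
    for label in sorted(groups):
        pooled = np.concatenate(groups[label])
        summary = descriptive_summary(TLProfile(f"group:{label}", pooled))
        result[label] = (counts[label], summary)
    return result
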