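"""Seeded generator of Q-FISH-like fluorescence datasets and cohorts.

Real per-telomere Q-FISH data are right-skewed, positive, decline with age
on average, and contain ND dropout.  The generator emulates exactly that
statistical structure: per-slot telomere lengths are drawn from a log-normal
whose mean declines linearly with age,

    mean_kb(age) = mean_tl_at_20_kb + decline_kb_per_year · (age − 20)

(floored at 0.5 kb) with a fixed per-telomere coefficient of variation, and
a small fraction of slots is set to ND.  Intensities are emitted on the
calibration standard's scale — ``intensity = TL_kb / 7 × standard mean`` —
so the default calibration inverts the simulation exactly, which makes
round-trip tests sharp.

Cohort generation mirrors a typical adult reference population: ages uniform
on a range (21–82 by default) and a male fraction of 52.3%.  Everything is
deterministic under a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np

from telostat.data_model import (
    MISSING,
    FluorescenceDataset,
    IndividualRecord,
    TelomereMeasurement,
    build_measurement_grid,
)
from telostat.errors import DomainError

_STANDARD_KB = 7.0  # simulated intensities are on the default-standard scale

#: Name syllables used to build deterministic synthetic participant names.
_SYLLABLES = (
    "BA", "CE", "DI", "FO", "GU", "HA", "KE", "LI", "MO", "NU",
    "PA", "RE", "SI", "TO", "VU", "ZA",
)


@dataclass(frozen=True)
class SyntheticParams:
    """Generator settings; defaults describe the emulated study conditions.

    ``mean_tl_at_20_kb`` and ``decline_kb_per_year`` set the linear
    age-decline of the per-telomere mean; ``cv`` the per-telomere spread;
    ``nd_rate`` the ND dropout fraction; ``male_fraction`` the cohort sex
    ratio.  ``chromosome_offsets_kb`` optionally adds a fixed per-chromosome
    shift (23 values) for testing per-chromosome reports.
    """

    mean_tl_at_20_kb: float = 9.0
    decline_kb_per_year: float = -0.04
    cv: float = 0.35
    nd_rate: float = 0.02
    n_metaphases: int = 10
    standard_mean_intensity: float = 100.0
    male_fraction: float = 0.523
    sampling_date: date = date(2018, 6, 15)
    chromosome_offsets_kb: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.nd_rate < 1.0:
            raise DomainError("nd_rate must be in [0, 1)")
        if self.cv <= 0:
            raise DomainError("cv must be positive")
        if self.n_metaphases < 1:
            raise DomainError("n_metaphases must be ≥1")
        if self.standard_mean_intensity <= 0:
            raise DomainError("standard_mean_intensity must be positive")
        if self.chromosome_offsets_kb is not None and len(self.chromosome_offsets_kb) != 23:
            raise DomainError("chromosome_offsets_kb needs exactly 23 values")

    def mean_kb_at(self, age: float) -> float:
        mean = self.mean_tl_at_20_kb + self.decline_kb_per_year * (age - 20.0)
        return max(mean, 0.5)


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given arithmetic mean and CV."""
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def simulate_individual(
    age: float,
    params: SyntheticParams = SyntheticParams(),
    rng: np.random.Generator | int | None = None,
    sample_code: str = "Sample001",
) -> FluorescenceDataset:
    """One individual's full measurement grid of simulated intensities.

    Per-slot TL (kb) is log-normal with the age-dependent mean and the
    parameter CV; intensity = TL/7 kb × standard mean intensity, so applying
    the default 7-kb standard recovers the simulated lengths exactly.  A
    fraction ``nd_rate`` of slots is ND.
    """
    if age < 0:
        raise DomainError("age must be non-negative")
    if params.mean_kb_at(age) <= 0:
        raise DomainError("age-adjusted mean TL must be positive")
    rng = np.random.default_rng(rng)
    grid = build_measurement_grid(params.n_metaphases)
    n = len(grid)

    if params.chromosome_offsets_kb is None:
        mu, sigma = _lognormal_params(params.mean_kb_at(age), params.cv)
        tl_kb = rng.lognormal(mu, sigma, size=n)
    else:
        tl_kb = np.empty(n)
        draws = rng.standard_normal(n)
        for i, (chrom, _, _, _) in enumerate(grid):
            mean = max(params.mean_kb_at(age) + params.chromosome_offsets_kb[chrom - 1], 0.5)
            mu, sigma = _lognormal_params(mean, params.cv)
            tl_kb[i] = math.exp(mu + sigma * draws[i])

    nd_mask = rng.random(n) < params.nd_rate
    intensity = tl_kb / _STANDARD_KB * params.standard_mean_intensity
    measurements = [
        TelomereMeasurement(
            chrom, hom, meta, end,
            intensity=MISSING if nd_mask[i] else float(intensity[i]),
        )
        for i, (chrom, hom, meta, end) in enumerate(grid)
    ]
    return FluorescenceDataset(
        sample_code, measurements, n_metaphases=params.n_metaphases
    )


def _synthetic_name(rng: np.random.Generator) -> str:
    k = int(rng.integers(2, 4))
    return "".join(_SYLLABLES[int(i)] for i in rng.integers(0, len(_SYLLABLES), k))


def simulate_population(
    n: int,
    age_range: tuple[float, float] = (21.0, 82.0),
    params: SyntheticParams = SyntheticParams(),
    seed: int | None = None,
) -> list[tuple[FluorescenceDataset, IndividualRecord]]:
    """A synthetic cohort with demographics, codes and dates.

    Ages are uniform on ``age_range``; sex is drawn with the configured male
    fraction; birth dates are back-computed from the fixed sampling date.
    Two runs with the same seed produce identical cohorts.
    """
    if n < 1:
        raise DomainError("population size must be ≥1")
    lo, hi = age_range
    if hi < lo or lo < 0:
        raise DomainError(f"invalid age range {age_range}")
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(1, n + 1):
        age = float(rng.uniform(lo, hi))
        sex = "M" if rng.random() < params.male_fraction else "F"
        birth = params.sampling_date - timedelta(days=round(age * 365.25))
        record = IndividualRecord(
            index=i,
            first_name=_synthetic_name(rng),
            surname=_synthetic_name(rng),
            birth_date=birth,
            sampling_date=params.sampling_date,
            analysis_date=params.sampling_date + timedelta(days=7),
            sex=sex,
        )
        dataset = simulate_individual(
            age, params, rng=rng, sample_code=record.reference_code
        )
        dataset.individual = record
        cohort.append((dataset, record))
    return cohort
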