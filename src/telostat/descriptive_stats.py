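"""Individual-level telomere length statistics.

Implements the descriptive layer of the pipeline: the 0–100% percentile grid
in 5% steps, quartiles by two engines, the short-telomere (TLS) subset, the
extreme-telomere counts and the 0.5-kb histogram.

Two quartile engines are provided deliberately.  The *linear-interpolation*
engine is the inclusive spreadsheet ``PERCENTILE`` rule (quantile "type 7"):
with sorted values v[1..n] and rank ``h = 1 + (n-1)*p/100``, the percentile
is ``v[⌊h⌋] + (h-⌊h⌋)·(v[⌊h⌋+1] - v[⌊h⌋])``.  The *Tukey's hinges* engine
folds the sample: the lower/upper hinge is the median of the lower/upper
half, each half including the overall median element when n is odd.  The two
engines give exactly the same median on every dataset (both reduce to the
standard sample median) but can differ at the quartiles — the basis of
cross-package accuracy comparisons between statistics tools.

The short-telomere subset (TLS) keeps values strictly above the sample
minimum and strictly below the 20th percentile, so it can never contain more
than 20% of the sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from telostat.data_model import FluorescenceDataset, is_missing
from telostat.errors import ConfigError, DomainError

PERCENTILE_GRID_LEVELS: tuple[int, ...] = tuple(range(0, 101, 5))

DEFAULT_SHORT_EXTREME_KB = 3.0
DEFAULT_LONG_EXTREME_KB = 20.0


@dataclass
class TLProfile:
    """An individual's calibrated telomere lengths in bases, ND excluded."""

    sample_code: str
    tl_bases: np.ndarray
    n_slots: int = 0

    def __post_init__(self) -> None:
        self.tl_bases = np.asarray(self.tl_bases, dtype=float)
        if np.any(np.isnan(self.tl_bases)):
            raise DomainError("TLProfile must not contain MISSING values")
        if np.any(self.tl_bases < 0):
            raise DomainError("telomere lengths must be non-negative")
        if self.n_slots == 0:
            self.n_slots = self.tl_bases.size
        if self.tl_bases.size > self.n_slots:
            raise DomainError("n_valid exceeds n_slots")

    @property
    def n_valid(self) -> int:
        return int(self.tl_bases.size)

    @classmethod
    def from_dataset(cls, dataset: FluorescenceDataset) -> "TLProfile":
        """Extract the valid calibrated lengths from a calibrated dataset."""
        values = [
            m.tl_bases for m in dataset.measurements if not is_missing(m.tl_bases)
        ]
        return cls(dataset.sample_code, np.array(values, dtype=float), dataset.n_slots)


@dataclass
class DescriptiveSummary:
    """Count/mean/min/max, both quartile engines and the 5%-step grid."""

    n: int
    mean: float
    median: float
    q1_linear: float
    q3_linear: float
    q1_tukey: float
    q3_tukey: float
    min: float
    max: float
    percentile_grid: dict[int, float] = field(default_factory=dict)


@dataclass
class HistogramResult:
    """Frequency table of TL in fixed-width bins with inclusive upper edges.

    Bin *i* covers ``(edges[i] - bin_width, edges[i]]`` except the first,
    which also includes 0.  ``median_bin_index`` / ``p20_bin_index`` locate
    the bins holding the sample median and 20th percentile.
    """

    bin_width: float
    bin_upper_edges: np.ndarray
    counts: np.ndarray
    relative: np.ndarray
    cumulative: np.ndarray
    median_bin_index: int
    p20_bin_index: int


@dataclass
class ExtremeCounts:
    """Counts of extremely short (<3 kb) and extremely long (>20 kb) telomeres."""

    n: int
    n_short_extreme: int
    n_long_extreme: int
    low_kb: float = DEFAULT_SHORT_EXTREME_KB
    high_kb: float = DEFAULT_LONG_EXTREME_KB

    @property
    def pct_short_extreme(self) -> float:
        return 100.0 * self.n_short_extreme / self.n if self.n else 0.0

    @property
    def pct_long_extreme(self) -> float:
        return 100.0 * self.n_long_extreme / self.n if self.n else 0.0


def percentile_linear(values, p: float) -> float:
    """Inclusive linear-interpolation percentile (spreadsheet PERCENTILE).

    ``p`` is on the 0–100 scale; ``p=0`` and ``p=100`` return the sample
    minimum and maximum exactly.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise DomainError("percentile of an empty sample is undefined")
    if not 0.0 <= p <= 100.0:
        raise DomainError(f"percentile level must be in [0, 100], got {p}")
    h = (v.size - 1) * (p / 100.0)
    lo = math.floor(h)
    frac = h - lo
    if lo + 1 >= v.size:
        return float(v[-1])
    return float(v[lo] + frac * (v[lo + 1] - v[lo]))


def _median_sorted(v: np.ndarray) -> float:
    n = v.size
    mid = n // 2
    if n % 2:
        return float(v[mid])
    # same lerp expression as percentile_linear at p=50, so both engines
    # return a bit-identical median
    return float(v[mid - 1] + 0.5 * (v[mid] - v[mid - 1]))


def tukey_hinges(values) -> tuple[float, float, float]:
    """Tukey's hinges: (lower hinge, median, upper hinge).

    The sample is folded at the median; each half includes the median
    element when n is odd, and the hinges are the medians of the halves
    (the quartile definition of the five-number summary).
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise DomainError("hinges of an empty sample are undefined")
    n = v.size
    mid = n // 2
    if n % 2:
        lower, upper = v[: mid + 1], v[mid:]
    else:
        lower, upper = v[:mid], v[mid:]
    return _median_sorted(lower), _median_sorted(v), _median_sorted(upper)


def descriptive_summary(profile: TLProfile) -> DescriptiveSummary:
    """Full descriptive summary of a TL (or TLS) profile.

    Populates the 0–100 grid in 5% steps from the linear engine and reports
    quartiles from both engines side by side.
    """
    v = profile.tl_bases
    if v.size == 0:
        raise DomainError(f"profile {profile.sample_code} has no valid measurements")
    grid = {p: percentile_linear(v, p) for p in PERCENTILE_GRID_LEVELS}
    hinge_lo, med, hinge_hi = tukey_hinges(v)
    return DescriptiveSummary(
        n=profile.n_valid,
        mean=float(np.mean(v)),
        median=med,
        q1_linear=percentile_linear(v, 25),
        q3_linear=percentile_linear(v, 75),
        q1_tukey=hinge_lo,
        q3_tukey=hinge_hi,
        min=float(np.min(v)),
        max=float(np.max(v)),
        percentile_grid=grid,
    )


def detect_short_telomeres(profile: TLProfile) -> TLProfile:
    """The TLS subset: values strictly between the minimum and P20.

    Both bounds are strict (``TL > min`` and ``TL < P20``), so ties at the
    minimum or at exactly the 20th percentile are excluded and the subset
    holds strictly fewer than 20% of the values.  May be empty.
    """
    v = profile.tl_bases
    if v.size == 0:
        raise DomainError(f"profile {profile.sample_code} has no valid measurements")
    p20 = percentile_linear(v, 20)
    lo = float(np.min(v))
    subset = v[(v > lo) & (v < p20)]
    return TLProfile(profile.sample_code + "S", subset, n_slots=profile.n_slots)


def classify_extremes(
    profile: TLProfile,
    low_kb: float = DEFAULT_SHORT_EXTREME_KB,
    high_kb: float = DEFAULT_LONG_EXTREME_KB,
) -> ExtremeCounts:
    """Count extremely short (< low_kb) and extremely long (> high_kb) values.

    Both comparisons are strict; thresholds are in kb, profile values in
    bases.
    """
    if low_kb >= high_kb:
        raise ConfigError(f"low threshold {low_kb} must be below high {high_kb}")
    v = profile.tl_bases
    return ExtremeCounts(
        n=v.size,
        n_short_extreme=int(np.sum(v < 1000.0 * low_kb)),
        n_long_extreme=int(np.sum(v > 1000.0 * high_kb)),
        low_kb=low_kb,
        high_kb=high_kb,
    )


def histogram_tl(profile: TLProfile, bin_width: float = 500.0) -> HistogramResult:
    """Histogram of TL in fixed-width bins with inclusive upper edges.

    Edges are the multiples of ``bin_width`` covering [0, max]; a value v
    falls in the bin whose upper edge is the smallest multiple ≥ v (so bins
    are ``(prev, upper]``, with 0 placed in the first bin).  Relative and
    cumulative frequencies and the bins holding the median and P20 are
    reported.
    """
    if bin_width <= 0:
        raise ConfigError(f"bin_width must be positive, got {bin_width}")
    v = profile.tl_bases
    if v.size == 0:
        raise DomainError(f"profile {profile.sample_code} has no valid measurements")

    def bin_index(x: float) -> int:
        return max(0, math.ceil(x / bin_width) - 1)

    n_bins = bin_index(float(np.max(v))) + 1
    edges = bin_width * np.arange(1, n_bins + 1)
    counts = np.zeros(n_bins, dtype=int)
    for x in v:
        counts[bin_index(float(x))] += 1
    relative = counts / v.size
    cumulative = np.cumsum(relative)
    cumulative[-1] = 1.0  # guard against float round-off in the last bin
    return HistogramResult(
        bin_width=float(bin_width),
        bin_upper_edges=edges,
        counts=counts,
        relative=relative,
        cumulative=cumulative,
        median_bin_index=bin_index(percentile_linear(v, 50)),
        p20_bin_index=bin_index(percentile_linear(v, 20)),
    )
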