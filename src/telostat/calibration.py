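"""Two-level calibration of fluorescence intensities to telomere length.

Level 1 corrects for day-to-day lamp/alignment drift using images of
reference fluorescent beads acquired before each session: every intensity is
multiplied by ``reference_intensity / session_intensity``.

Level 2 converts corrected intensities to kilobases through a calibration
standard — the L5178Y-S mouse lymphoma line, whose telomere length is stable
and known (≈7 kb).  The conversion is a zero-intercept proportionality
through the standard's operating point::

    TL_kb = known_tl_kb * intensity / mean_intensity

Both factors are purely multiplicative, so bead correction and slide
normalization commute; MISSING (ND) values propagate unchanged through both.
Internal storage downstream is in bases (1000 × kb).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np

from telostat.data_model import (
    MISSING,
    FluorescenceDataset,
    TelomereMeasurement,
    is_missing,
)
from telostat.errors import DomainError, ValidationError

KB_PER_BASE = 1e-3


@dataclass(frozen=True)
class BeadReference:
    """Reference vs session bead intensity for lamp-drift correction."""

    reference_intensity: float
    session_intensity: float
    session_date: date | None = None

    def __post_init__(self) -> None:
        if self.reference_intensity <= 0 or self.session_intensity <= 0:
            raise DomainError("bead intensities must be positive")

    @property
    def factor(self) -> float:
        return self.reference_intensity / self.session_intensity


@dataclass(frozen=True)
class CalibrationStandard:
    """Cell line with known telomere length used to anchor the kb scale.

    Defaults describe L5178Y-S with its ≈7 kb telomeres; ``mean_intensity``
    is the mean fluorescence of the standard in the same session, in AU.
    """

    mean_intensity: float
    known_tl_kb: float = 7.0
    name: str = "L5178Y-S"
    analysis_date: date | None = None

    def __post_init__(self) -> None:
        if self.mean_intensity <= 0:
            raise DomainError("standard mean_intensity must be positive")
        if self.known_tl_kb <= 0:
            raise DomainError("standard known_tl_kb must be positive")

    def rescaled(self, factor: float) -> "CalibrationStandard":
        """Standard with mean intensity divided by a session factor."""
        return CalibrationStandard(
            self.mean_intensity / factor, self.known_tl_kb, self.name, self.analysis_date
        )


def bead_correct(intensities, beads: BeadReference):
    """Apply the session bead factor to a vector of intensities.

    Accepts any array-like of AU values with NaN for MISSING; MISSING
    propagates.  Returns a float ndarray.
    """
    values = np.asarray(intensities, dtype=float)
    return values * beads.factor


def intensity_to_kb(intensity, standard: CalibrationStandard):
    """Convert intensity (scalar or vector, AU) to telomere length in kb.

    Linear through the origin, anchored at the standard's
    ``(mean_intensity, known_tl_kb)`` point.  MISSING propagates; negative
    intensities are rejected.
    """
    values = np.asarray(intensity, dtype=float)
    if np.any(values[~np.isnan(values)] < 0):
        raise ValidationError("negative intensity cannot be calibrated")
    result = standard.known_tl_kb * values / standard.mean_intensity
    if np.ndim(intensity) == 0:
        return float(result)
    return result


def calibrate_dataset(
    dataset: FluorescenceDataset,
    standard: CalibrationStandard,
    beads: BeadReference | None = None,
) -> FluorescenceDataset:
    """Return a new dataset with ``tl_bases`` filled in for every reading.

    ND measurements stay MISSING.  The input dataset is not mutated.
    """
    factor = beads.factor if beads is not None else 1.0
    calibrated = []
    for m in dataset.measurements:
        if is_missing(m.intensity):
            calibrated.append(m)
            continue
        kb = intensity_to_kb(m.intensity * factor, standard)
        calibrated.append(
            TelomereMeasurement(
                m.chromosome, m.homolog, m.metaphase, m.arm_end,
                intensity=m.intensity, tl_bases=1000.0 * kb,
            )
        )
    return FluorescenceDataset(
        dataset.sample_code,
        calibrated,
        n_metaphases=dataset.n_metaphases,
        individual=dataset.individual,
    )
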