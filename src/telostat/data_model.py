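"""Domain types and table parsing for per-telomere fluorescence data.

A metaphase spread gives four telomere signals per chromosome (the two ends
of each of the two chromatids, labelled p1, p2, q1, q2).  One individual's
dataset indexes every fluorescence reading by the tuple
``(chromosome, homolog, metaphase, arm_end)``; with 23 chromosomes, two
homologs, four arm ends and ten metaphases that is 1840 measurement slots.
Readings indistinguishable from background carry the code ``ND`` (not
detected) and are represented here as :data:`MISSING` (NaN).

This module also implements the participant coding scheme (a sequential
reference code such as ``Sample012`` plus an identification code built from
name, birth year, sex and repeat index) and date arithmetic for chronological
age.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from telostat.errors import (
    DomainError,
    IntegrityError,
    ParseError,
    ValidationError,
)

#: Sentinel for a measurement coded ND (not detected) in the source table.
MISSING: float = math.nan

HOMOLOGS = ("a", "b")
ARM_ENDS = ("p1", "p2", "q1", "q2")
N_CHROMOSOMES = 23

#: Aliases accepted for the four index columns of a raw intensity table.
_COLUMN_ALIASES = {
    "chromosome": "chromosome",
    "chr": "chromosome",
    "1o2o": "homolog",
    "pair": "homolog",
    "homolog": "homolog",
    "metaphase": "metaphase",
    "tails": "arm_end",
    "tail": "arm_end",
    "arm_end": "arm_end",
}


def is_missing(value: float | None) -> bool:
    """True if *value* represents an ND / absent measurement."""
    return value is None or (isinstance(value, float) and math.isnan(value))


@dataclass(frozen=True)
class TelomereMeasurement:
    """One fluorescence reading at a unique (chromosome, homolog, metaphase,
    arm end) address.

    ``intensity`` is in arbitrary fluorescence units (AU); ``tl_bases`` is the
    calibrated telomere length in bases, filled in by the calibration stage.
    Both are :data:`MISSING` for ND readings.
    """

    chromosome: int
    homolog: str
    metaphase: int
    arm_end: str
    intensity: float = MISSING
    tl_bases: float = MISSING

    def __post_init__(self) -> None:
        if not 1 <= self.chromosome <= N_CHROMOSOMES:
            raise DomainError(f"chromosome must be 1–{N_CHROMOSOMES}, got {self.chromosome}")
        if self.homolog not in HOMOLOGS:
            raise DomainError(f"homolog must be one of {HOMOLOGS}, got {self.homolog!r}")
        if self.metaphase < 1:
            raise DomainError(f"metaphase must be ≥1, got {self.metaphase}")
        if self.arm_end not in ARM_ENDS:
            raise DomainError(f"arm_end must be one of {ARM_ENDS}, got {self.arm_end!r}")
        if not is_missing(self.intensity) and self.intensity < 0:
            raise ValidationError(f"negative intensity {self.intensity}")
        if is_missing(self.intensity) and not is_missing(self.tl_bases):
            raise ValidationError("tl_bases must be MISSING when intensity is MISSING")

    @property
    def key(self) -> tuple[int, str, int, str]:
        return (self.chromosome, self.homolog, self.metaphase, self.arm_end)


@dataclass(frozen=True)
class IndividualRecord:
    """Demographic record for one participant and one examination.

    ``repeat_index`` counts repeated examinations of the same person (1st,
    2nd, ... repeat); ``exposure_flags`` carries tags such as ``pesticides``,
    ``supplements`` or ``narcotics``.
    """

    index: int
    first_name: str
    surname: str
    birth_date: date
    sampling_date: date
    analysis_date: date
    sex: str
    repeat_index: int = 1
    exposure_flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.index <= 0:
            raise DomainError(f"participant index must be positive, got {self.index}")
        if self.repeat_index <= 0:
            raise DomainError(f"repeat_index must be positive, got {self.repeat_index}")
        if self.sex not in ("M", "F"):
            raise DomainError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.sampling_date < self.birth_date:
            raise DomainError("sampling_date precedes birth_date")
        if self.analysis_date < self.sampling_date:
            raise DomainError("analysis_date precedes sampling_date")

    @property
    def reference_code(self) -> str:
        return f"Sample{self.index:03d}"

    @property
    def identification_code(self) -> str:
        return make_codes(
            self.index,
            self.first_name,
            self.surname,
            self.birth_date.year,
            self.sex,
            self.repeat_index,
        )[1]

    @property
    def age_at_sampling(self) -> float:
        return chronological_age(self.birth_date, self.sampling_date)


@dataclass
class FluorescenceDataset:
    """All telomere fluorescence measurements of one individual.

    A complete dataset covers the full measurement grid
    (23 chromosomes × 2 homologs × 4 arm ends × ``n_metaphases``).
    """

    sample_code: str
    measurements: list[TelomereMeasurement]
    n_metaphases: int = 10
    individual: IndividualRecord | None = None

    def __post_init__(self) -> None:
        seen: set[tuple] = set()
        for m in self.measurements:
            if m.key in seen:
                raise IntegrityError(
                    f"duplicate measurement slot {m.key} in {self.sample_code}"
                )
            seen.add(m.key)

    @property
    def n_slots(self) -> int:
        return N_CHROMOSOMES * len(HOMOLOGS) * len(ARM_ENDS) * self.n_metaphases

    @property
    def n_valid(self) -> int:
        return sum(not is_missing(m.intensity) for m in self.measurements)

    def intensities(self) -> list[float]:
        """Intensities in grid order, MISSING values included as NaN."""
        return [m.intensity for m in self.measurements]


def build_measurement_grid(
    n_metaphases: int,
) -> list[tuple[int, str, int, str]]:
    """Full index grid of one individual's measurement slots.

    Returns the 23 × 2 × 4 × ``n_metaphases`` tuples
    ``(chromosome, homolog, metaphase, arm_end)`` in lexicographic order
    (chromosome 1–23, homolog a/b, metaphase 1–n, arm end p1,p2,q1,q2).
    With the default ten metaphases this is the 1840-slot grid.
    """
    if n_metaphases < 1:
        raise DomainError(f"n_metaphases must be ≥1, got {n_metaphases}")
    return [
        (chrom, hom, meta, end)
        for chrom in range(1, N_CHROMOSOMES + 1)
        for hom in HOMOLOGS
        for meta in range(1, n_metaphases + 1)
        for end in ARM_ENDS
    ]


def make_codes(
    index: int,
    first_name: str,
    surname: str,
    birth_year: int,
    sex: str,
    repeat_index: int,
) -> tuple[str, str]:
    """Reference and identification codes for a participant examination.

    The reference code is ``Sample`` plus the zero-padded 3-digit series
    index.  The identification code concatenates the first three letters of
    the first name and surname (uppercased; names shorter than three letters
    are right-padded with ``_``), the 4-digit birth year, the sex letter and
    ``R`` plus the repeat index, e.g. ``("Sample012", "SMIJOH1970MR1")``.
    """
    if index <= 0:
        raise DomainError(f"index must be positive, got {index}")
    if repeat_index <= 0:
        raise DomainError(f"repeat_index must be positive, got {repeat_index}")
    if sex not in ("M", "F"):
        raise DomainError(f"sex must be 'M' or 'F', got {sex!r}")
    if not first_name or not surname:
        raise DomainError("names must be non-empty")

    def _tri(name: str) -> str:
        return name.upper()[:3].ljust(3, "_")

    reference = f"Sample{index:03d}"
    ident = f"{_tri(first_name)}{_tri(surname)}{birth_year:04d}{sex}R{repeat_index}"
    return reference, ident


def chronological_age(birth_date: date, sampling_date: date) -> float:
    """Age in decimal years: day difference divided by 365.25."""
    if sampling_date < birth_date:
        raise DomainError("sampling_date precedes birth_date")
    return (sampling_date - birth_date).days / 365.25


# ---------------------------------------------------------------------------
# Table parsing and serialization


def _parse_chromosome(value: object, row: int) -> int:
    text = str(value).strip()
    if text.lower().startswith("chr"):
        text = text[3:]
    try:
        chrom = int(text)
    except ValueError:
        raise ParseError(f"row {row}: unknown chromosome label {value!r}") from None
    if not 1 <= chrom <= N_CHROMOSOMES:
        raise ParseError(f"row {row}: chromosome {value!r} outside Chr01–Chr23")
    return chrom


def _parse_intensity(value: object, row: int, column: str) -> float:
    if value is None:
        return MISSING
    text = str(value).strip()
    if text == "" or text.upper() == "ND" or text.lower() == "nan":
        return MISSING
    try:
        intensity = float(text)
    except ValueError:
        raise ParseError(
            f"row {row}, column {column!r}: cannot read intensity {value!r}"
        ) from None
    if intensity < 0:
        raise ValidationError(
            f"row {row}, column {column!r}: negative intensity {intensity}"
        )
    return intensity


def parse_fluorescence_table(
    rows: pd.DataFrame | str | Path,
    n_metaphases: int = 10,
) -> list[FluorescenceDataset]:
    """Parse a raw intensity table into one dataset per sample column.

    The table layout mirrors the raw Q-FISH export: four index columns
    (``Chromosome``, ``1o2o``/``Pair``, ``Metaphase``, ``Tails``/``Tail``)
    followed by one intensity column per sample.  ``ND`` and blank cells
    become :data:`MISSING`; duplicate index tuples raise
    :class:`~telostat.errors.IntegrityError`; unknown labels raise
    :class:`~telostat.errors.ParseError` naming the offending row.

    ``rows`` may be a DataFrame, a CSV/TSV path, or an ``.xlsx`` path (the
    sheet named ``ILLUMINANCE`` is used if present).
    """
    frame = _load_frame(rows)
    rename: dict[str, str] = {}
    for col in frame.columns:
        canon = _COLUMN_ALIASES.get(str(col).strip().lower())
        if canon is not None and canon not in rename.values():
            rename[col] = canon
    frame = frame.rename(columns=rename)
    required = {"chromosome", "homolog", "metaphase", "arm_end"}
    missing_cols = required - set(frame.columns)
    if missing_cols:
        raise ParseError(f"missing index columns: {sorted(missing_cols)}")

    sample_columns = [c for c in frame.columns if c not in required]
    per_sample: dict[str, list[TelomereMeasurement]] = {
        str(c): [] for c in sample_columns
    }
    seen: set[tuple] = set()
    for pos, record in enumerate(frame.itertuples(index=False), start=1):
        row = dict(zip(frame.columns, record))
        chrom = _parse_chromosome(row["chromosome"], pos)
        hom = str(row["homolog"]).strip().lower()
        if hom not in HOMOLOGS:
            raise ParseError(f"row {pos}: unknown homolog label {row['homolog']!r}")
        try:
            meta = int(row["metaphase"])
        except (TypeError, ValueError):
            raise ParseError(f"row {pos}: bad metaphase {row['metaphase']!r}") from None
        if not 1 <= meta <= n_metaphases:
            raise ParseError(f"row {pos}: metaphase {meta} outside 1–{n_metaphases}")
        end = str(row["arm_end"]).strip().lower()
        if end not in ARM_ENDS:
            raise ParseError(f"row {pos}: unknown tail label {row['arm_end']!r}")
        key = (chrom, hom, meta, end)
        if key in seen:
            raise IntegrityError(f"row {pos}: duplicate index tuple {key}")
        seen.add(key)
        for col in sample_columns:
            intensity = _parse_intensity(row[col], pos, str(col))
            per_sample[str(col)].append(
                TelomereMeasurement(chrom, hom, meta, end, intensity)
            )

    return [
        FluorescenceDataset(code, measurements, n_metaphases=n_metaphases)
        for code, measurements in per_sample.items()
    ]


def _load_frame(rows: pd.DataFrame | str | Path) -> pd.DataFrame:
    if isinstance(rows, pd.DataFrame):
        return rows
    path = Path(rows)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        sheets = pd.ExcelFile(path).sheet_names
        sheet = "ILLUMINANCE" if "ILLUMINANCE" in sheets else 0
        return pd.read_excel(path, sheet_name=sheet, dtype=object)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep, dtype=object, keep_default_na=False)


def to_tidy(datasets: Iterable[FluorescenceDataset]) -> pd.DataFrame:
    """Tidy long-format table: one row per measurement per sample.

    MISSING intensities serialize as the string ``ND`` so that the tidy
    round-trip preserves every ND marker.
    """
    records = []
    for ds in datasets:
        for m in ds.measurements:
            records.append(
                {
                    "sample": ds.sample_code,
                    "chromosome": m.chromosome,
                    "homolog": m.homolog,
                    "metaphase": m.metaphase,
                    "arm_end": m.arm_end,
                    "intensity": "ND" if is_missing(m.intensity) else repr(m.intensity),
                }
            )
    return pd.DataFrame.from_records(
        records,
        columns=["sample", "chromosome", "homolog", "metaphase", "arm_end", "intensity"],
    )


def from_tidy(frame: pd.DataFrame | str | Path, n_metaphases: int = 10) -> list[FluorescenceDataset]:
    """Inverse of :func:`to_tidy`; intensities round-trip bit-exactly."""
    if not isinstance(frame, pd.DataFrame):
        frame = pd.read_csv(frame, dtype=object, keep_default_na=False)
    datasets = []
    for code, group in frame.groupby("sample", sort=False):
        measurements = [
            TelomereMeasurement(
                _parse_chromosome(r["chromosome"], pos),
                str(r["homolog"]),
                int(r["metaphase"]),
                str(r["arm_end"]),
                _parse_intensity(r["intensity"], pos, "intensity"),
            )
            for pos, (_, r) in enumerate(group.iterrows(), start=1)
        ]
        datasets.append(
            FluorescenceDataset(str(code), measurements, n_metaphases=n_metaphases)
        )
    return datasets


def parse_demographics(frame: pd.DataFrame | str | Path) -> list[IndividualRecord]:
    """Parse a demographics table into records.

    Expected columns: ``index, first_name, surname, birth_date,
    sampling_date, analysis_date, sex`` and optionally ``repeat_index`` and
    ``exposure_flags`` (semicolon-separated tags).  Dates must be ISO-8601;
    ambiguous day/month forms are rejected.
    """
    if not isinstance(frame, pd.DataFrame):
        frame = pd.read_csv(frame, dtype=object, keep_default_na=False)
    records = []
    for pos, (_, row) in enumerate(frame.iterrows(), start=1):
        try:
            birth = date.fromisoformat(str(row["birth_date"]).strip())
            sampling = date.fromisoformat(str(row["sampling_date"]).strip())
            analysis = date.fromisoformat(str(row["analysis_date"]).strip())
        except ValueError:
            raise ParseError(
                f"row {pos}: dates must be ISO-8601 (YYYY-MM-DD); "
                "ambiguous forms like 12/1/1970 are rejected"
            ) from None
        flags = str(row.get("exposure_flags", "") or "").strip()
        records.append(
            IndividualRecord(
                index=int(row["index"]),
                first_name=str(row["first_name"]),
                surname=str(row["surname"]),
                birth_date=birth,
                sampling_date=sampling,
                analysis_date=analysis,
                sex=str(row["sex"]).strip().upper(),
                repeat_index=int(row.get("repeat_index", 1) or 1),
                exposure_flags=frozenset(
                    t.strip() for t in flags.split(";") if t.strip() and t.strip() != "none"
                ),
            )
        )
    return records


def demographics_to_frame(records: Sequence[IndividualRecord]) -> pd.DataFrame:
    """Serialize records to the demographics table layout."""
    return pd.DataFrame(
        {
            "index": [r.index for r in records],
            "reference_code": [r.reference_code for r in records],
            "identification_code": [r.identification_code for r in records],
            "first_name": [r.first_name for r in records],
            "surname": [r.surname for r in records],
            "birth_date": [r.birth_date.isoformat() for r in records],
            "sampling_date": [r.sampling_date.isoformat() for r in records],
            "analysis_date": [r.analysis_date.isoformat() for r in records],
            "sex": [r.sex for r in records],
            "repeat_index": [r.repeat_index for r in records],
            "exposure_flags": [
                ";".join(sorted(r.exposure_flags)) or "none" for r in records
            ],
        }
    )
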