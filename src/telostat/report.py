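"""Individual text report: the full per-person analysis in one call.

``generate_report`` runs the whole pipeline for one individual — calibration,
TL and TLS summaries, the 0.5-kb histogram, extreme-telomere counts, medians
per chromosome and per arm end, and (when a nomogram is supplied) the
biological-age estimate — and renders a deterministic plain-text report plus
a machine-readable dict that serializes to JSON.  Every number in the text is
formatted from the same value the dict carries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from telostat.calibration import BeadReference, CalibrationStandard, calibrate_dataset
from telostat.data_model import FluorescenceDataset, IndividualRecord, is_missing
from telostat.descriptive_stats import (
    DescriptiveSummary,
    ExtremeCounts,
    HistogramResult,
    TLProfile,
    classify_extremes,
    descriptive_summary,
    detect_short_telomeres,
    histogram_tl,
)
from telostat.errors import TelostatError
from telostat.nomogram_bioage import BioAgeEstimate, Nomogram, estimate_biological_age


@dataclass
class ReportBundle:
    sample_code: str
    individual: IndividualRecord | None
    summary_tl: DescriptiveSummary
    summary_tls: DescriptiveSummary | None  # None when the TLS subset is empty
    histogram: HistogramResult
    extremes: ExtremeCounts
    per_chromosome_medians: dict[int, float]
    per_arm_medians: dict[str, float]
    bioage: BioAgeEstimate | None
    text: str
    data: dict

    def to_json(self) -> str:
        return json.dumps(self.data, indent=2)


def _kb(bases: float) -> str:
    return f"{bases / 1000.0:.1f}"


def generate_report(
    dataset: FluorescenceDataset,
    standard: CalibrationStandard,
    beads: BeadReference | None = None,
    nomogram: Nomogram | None = None,
    chronological_age: float | None = None,
) -> ReportBundle:
    """Full individual report from a raw fluorescence dataset.

    The biological-age section is produced only when both a nomogram and a
    chronological age (or an attached demographic record) are available.
    """
    calibrated = calibrate_dataset(dataset, standard, beads)
    profile = TLProfile.from_dataset(calibrated)
    if profile.n_valid == 0:
        raise TelostatError(
            f"dataset {dataset.sample_code} has no valid measurements to report"
        )
    summary = descriptive_summary(profile)
    tls_profile = detect_short_telomeres(profile)
    summary_tls = (
        descriptive_summary(tls_profile) if tls_profile.n_valid else None
    )
    hist = histogram_tl(profile)
    extremes = classify_extremes(profile)

    by_chrom: dict[int, list[float]] = {}
    by_arm: dict[str, list[float]] = {}
    for m in calibrated.measurements:
        if is_missing(m.tl_bases):
            continue
        by_chrom.setdefault(m.chromosome, []).append(m.tl_bases)
        by_arm.setdefault(m.arm_end, []).append(m.tl_bases)
    chrom_medians = {c: float(np.median(v)) for c, v in sorted(by_chrom.items())}
    arm_medians = {a: float(np.median(v)) for a, v in sorted(by_arm.items())}
    missing_chroms = sorted(set(range(1, 24)) - set(chrom_medians))

    bioage: BioAgeEstimate | None = None
    age = chronological_age
    if age is None and dataset.individual is not None:
        age = dataset.individual.age_at_sampling
    if nomogram is not None and age is not None:
        bioage = estimate_biological_age(nomogram, summary.median, age)

    data = {
        "sample": dataset.sample_code,
        "n_slots": dataset.n_slots,
        "n_valid": profile.n_valid,
        "tl": _summary_dict(summary),
        "tls": _summary_dict(summary_tls) if summary_tls else None,
        "n_tls": tls_profile.n_valid,
        "extremes": {
            "n_short_extreme": extremes.n_short_extreme,
            "n_long_extreme": extremes.n_long_extreme,
            "pct_short_extreme": round(extremes.pct_short_extreme, 1),
            "pct_long_extreme": round(extremes.pct_long_extreme, 1),
            "low_kb": extremes.low_kb,
            "high_kb": extremes.high_kb,
        },
        "histogram": {
            "bin_width_bases": hist.bin_width,
            "upper_edges_bases": hist.bin_upper_edges.tolist(),
            "counts": hist.counts.tolist(),
            "median_bin_index": hist.median_bin_index,
            "p20_bin_index": hist.p20_bin_index,
        },
        "per_chromosome_median_bases": {str(c): v for c, v in chrom_medians.items()},
        "per_arm_median_bases": arm_medians,
        "chromosomes_without_data": missing_chroms,
        "bioage": None
        if bioage is None
        else {
            "chronological_age": round(bioage.chronological_age, 1),
            "biological_age": round(bioage.biological_age, 1),
            "nearest_level": bioage.nearest_level,
            "above_median": bioage.above_median,
            "hypothesis_warning": bioage.hypothesis_warning,
        },
    }
    text = _render_text(data)
    return ReportBundle(
        sample_code=dataset.sample_code,
        individual=dataset.individual,
        summary_tl=summary,
        summary_tls=summary_tls,
        histogram=hist,
        extremes=extremes,
        per_chromosome_medians=chrom_medians,
        per_arm_medians=arm_medians,
        bioage=bioage,
        text=text,
        data=data,
    )


def _summary_dict(s: DescriptiveSummary) -> dict:
    return {
        "n": s.n,
        "mean_bases": round(s.mean, 1),
        "median_bases": round(s.median, 1),
        "q1_linear_bases": round(s.q1_linear, 1),
        "q3_linear_bases": round(s.q3_linear, 1),
        "q1_tukey_bases": round(s.q1_tukey, 1),
        "q3_tukey_bases": round(s.q3_tukey, 1),
        "min_bases": round(s.min, 1),
        "max_bases": round(s.max, 1),
        "percentile_grid_bases": {str(p): round(v, 1) for p, v in s.percentile_grid.items()},
    }


def _render_text(d: dict) -> str:
    lines = [
        f"Telomere profile report — {d['sample']}",
        "=" * 50,
        f"Measurements: {d['n_valid']} valid of {d['n_slots']} slots",
        "",
        "Whole-genome telomere length (TL)",
        f"  mean   {_kb(d['tl']['mean_bases'])} kb    median {_kb(d['tl']['median_bases'])} kb",
        f"  range  {_kb(d['tl']['min_bases'])}–{_kb(d['tl']['max_bases'])} kb",
        f"  Q1/Q3 (linear interp.)  {_kb(d['tl']['q1_linear_bases'])} / {_kb(d['tl']['q3_linear_bases'])} kb",
        f"  Q1/Q3 (Tukey's hinges)  {_kb(d['tl']['q1_tukey_bases'])} / {_kb(d['tl']['q3_tukey_bases'])} kb",
        "",
    ]
    if d["tls"]:
        lines += [
            f"Short telomeres (TLS: > min and < P20): n = {d['n_tls']}",
            f"  mean   {_kb(d['tls']['mean_bases'])} kb    median {_kb(d['tls']['median_bases'])} kb",
            "",
        ]
    else:
        lines += ["Short telomeres (TLS): none detected", ""]
    ex = d["extremes"]
    lines += [
        f"Extremely short (<{ex['low_kb']:g} kb): {ex['n_short_extreme']} ({ex['pct_short_extreme']:.1f}%)",
        f"Extremely long  (>{ex['high_kb']:g} kb): {ex['n_long_extreme']} ({ex['pct_long_extreme']:.1f}%)",
        "",
        "Median TL per arm end (kb): "
        + ", ".join(f"{a}={_kb(v)}" for a, v in d["per_arm_median_bases"].items()),
        "Median TL per chromosome (kb):",
    ]
    chrom_items = list(d["per_chromosome_median_bases"].items())
    for i in range(0, len(chrom_items), 6):
        lines.append(
            "  " + "  ".join(f"Chr{int(c):02d}={_kb(v)}" for c, v in chrom_items[i : i + 6])
        )
    if d["chromosomes_without_data"]:
        lines.append(
            "  no data: " + ", ".join(f"Chr{c:02d}" for c in d["chromosomes_without_data"])
        )
    if d["bioage"]:
        b = d["bioage"]
        position = "above" if b["above_median"] else "below"
        lines += [
            "",
            "Biological age estimate",
            f"  chronological age {b['chronological_age']:.1f} y; "
            f"median TL {position} the population median curve",
            f"  nearest reference line: P{b['nearest_level']}",
            f"  estimated biological age {b['biological_age']:.1f} y"
            + ("  [warning: inversion contradicts median-position rule]" if b["hypothesis_warning"] else ""),
        ]
    lines.append("")
    return "\n".join(lines)
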