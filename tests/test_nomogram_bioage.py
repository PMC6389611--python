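"""Reference-curve construction, biological-age inversion, group pivots."""

from datetime import date

import numpy as np
import pytest

from telostat.data_model import IndividualRecord
from telostat.descriptive_stats import TLProfile, percentile_linear
from telostat.errors import ConfigError, DomainError, EstimationError
from telostat.nomogram_bioage import (
    Nomogram,
    build_nomogram,
    estimate_biological_age,
    group_summary,
)
from telostat.synthetic_data import SyntheticParams, simulate_individual


def linear_population(intercept=9000.0, slope=-40.0, spread=0.0, rng=None,
                      ages=None, n_values=100):
    """Individuals placed at decadal age-group midpoints whose values follow
    value = intercept + slope·age exactly (optional symmetric spread)."""
    ages = ages if ages is not None else [25, 35, 45, 55, 65, 75, 85]
    pop = []
    for age in ages:
        center = intercept + slope * age
        if spread:
            offsets = np.linspace(-spread, spread, n_values)
        else:
            offsets = np.zeros(n_values)
        pop.append((TLProfile(f"a{age}", center + offsets), float(age)))
    return pop


class TestBuildNomogram:
    def test_flat_population_degenerate_fit(self):
        pop = [
            (TLProfile(f"s{age}", np.full(50, 8000.0)), float(age))
            for age in (25, 35, 45, 55)
        ]
        nomo = build_nomogram(pop)
        assert np.all(nomo.curve_values == 8000.0)
        for fit in nomo.fit_per_level.values():
            assert fit.slope == 0.0
            assert fit.r_squared == 1.0
            assert fit.degenerate

    def test_exact_linear_recovery(self):
        nomo = build_nomogram(linear_population(9000.0, -40.0))
        fit = nomo.fit_per_level[50]
        assert fit.intercept == pytest.approx(9000.0, rel=1e-6)
        assert fit.slope == pytest.approx(-40.0, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_curves_monotone_across_levels_on_simulation(self):
        params = SyntheticParams(n_metaphases=2)
        rng = np.random.default_rng(11)
        pop = []
        for i in range(60):
            age = float(rng.uniform(21, 82))
            ds = simulate_individual(age, params, rng=rng)
            from telostat.calibration import CalibrationStandard, calibrate_dataset

            prof = TLProfile.from_dataset(
                calibrate_dataset(ds, CalibrationStandard(100.0))
            )
            pop.append((prof, age))
        nomo = build_nomogram(pop)
        for row in nomo.curve_values:
            assert np.all(np.diff(row) >= 0)

    def test_pooled_group_percentiles_match_oracle(self):
        pop = linear_population(9000.0, -40.0, spread=500.0)
        nomo = build_nomogram(pop, levels=(10, 50, 90))
        pooled = pop[0][0].tl_bases
        for j, lvl in enumerate(nomo.percentile_levels):
            assert nomo.curve_values[0, j] == pytest.approx(
                percentile_linear(pooled, lvl)
            )

    def test_fewer_than_two_groups_rejected(self):
        pop = [(TLProfile("s", np.full(10, 8000.0)), 25.0)]
        with pytest.raises(DomainError, match="2"):
            build_nomogram(pop)

    def test_empty_interior_group_named(self):
        pop = [
            (TLProfile("a", np.full(10, 9000.0)), 25.0),
            (TLProfile("b", np.full(10, 7000.0)), 65.0),
        ]
        with pytest.raises(DomainError, match="30–40"):
            build_nomogram(pop)

    def test_age_outside_edges_rejected(self):
        pop = [(TLProfile("a", np.full(10, 9000.0)), 95.0)]
        with pytest.raises(DomainError):
            build_nomogram(pop)

    def test_json_round_trip(self, tmp_path):
        nomo = build_nomogram(linear_population(spread=300.0))
        path = tmp_path / "nomo.json"
        nomo.to_json(path)
        back = Nomogram.from_json(path)
        assert back.source == nomo.source
        assert back.percentile_levels == nomo.percentile_levels
        assert np.allclose(back.curve_values, nomo.curve_values)
        assert back.fit_per_level[50].slope == nomo.fit_per_level[50].slope


class TestBioAge:
    def test_on_median_curve_is_fixed_point(self):
        nomo = build_nomogram(linear_population(9000.0, -40.0, spread=800.0))
        for age in (30.0, 47.5, 80.0):
            est = estimate_biological_age(nomo, 9000.0 - 40.0 * age, age)
            assert est.biological_age == pytest.approx(age, abs=1e-9)
            assert est.nearest_level == 50

    def test_inversion_of_known_line(self):
        nomo = build_nomogram(linear_population(9000.0, -50.0))
        est = estimate_biological_age(nomo, 8000.0, 22.0)
        assert est.biological_age == pytest.approx(20.0, abs=1e-9)

    def test_below_median_flags_older(self):
        nomo = build_nomogram(linear_population(9000.0, -40.0, spread=2000.0))
        age = 40.0
        est = estimate_biological_age(nomo, 9000.0 - 40.0 * age - 1700.0, age)
        assert not est.above_median
        assert est.biological_age > age
        assert not est.hypothesis_warning

    def test_monotone_in_median_within_nearest_curve_basin(self):
        """Strictly decreasing in median TL while the nearest reference line
        is unchanged (across basin switches the inversion re-anchors to a
        different line, so only piecewise monotonicity is guaranteed)."""
        nomo = build_nomogram(linear_population(9000.0, -40.0, spread=2000.0))
        values = np.linspace(5000.0, 11000.0, 80)
        estimates = [estimate_biological_age(nomo, v, 50.0) for v in values]
        for a, b in zip(estimates, estimates[1:]):
            if a.nearest_level == b.nearest_level and not (a.clamped or b.clamped):
                assert b.biological_age < a.biological_age

    def test_globally_monotone_for_single_curve_nomogram(self):
        nomo = build_nomogram(linear_population(9000.0, -40.0), levels=(50,))
        ages = [
            estimate_biological_age(nomo, v, 50.0).biological_age
            for v in np.linspace(6000.0, 8500.0, 40)
        ]
        assert all(b < a for a, b in zip(ages, ages[1:]))

    def test_nondecreasing_reference_line_rejected(self):
        nomo = build_nomogram(linear_population(7000.0, +10.0))
        with pytest.raises(EstimationError, match="non-decreasing"):
            estimate_biological_age(nomo, 7500.0, 40.0)

    def test_nonpositive_median_rejected(self):
        nomo = build_nomogram(linear_population())
        with pytest.raises(DomainError):
            estimate_biological_age(nomo, 0.0, 40.0)

    def test_estimate_clamped_to_age_range_margin(self):
        nomo = build_nomogram(linear_population(9000.0, -40.0), levels=(50,))
        est = estimate_biological_age(nomo, 8999.0, 25.0)  # implies age ≈ 0
        assert est.clamped
        assert est.biological_age == pytest.approx(nomo.age_min - 10.0)


def _record(index, sex="M", flags=(), age_years=30):
    sampling = date(2018, 6, 15)
    return IndividualRecord(
        index=index, first_name="AAA", surname="BBB",
        birth_date=date(sampling.year - age_years, 6, 15),
        sampling_date=sampling, analysis_date=sampling, sex=sex,
        exposure_flags=frozenset(flags),
    )


class TestGroupSummary:
    def test_sex_groups_counted(self):
        pop = [
            (TLProfile(f"s{i}", np.full(10, 8000.0 + i)), _record(i, sex))
            for i, sex in enumerate(["M", "M", "F", "F"], start=1)
        ]
        table = group_summary(pop, by="sex")
        assert set(table) == {"M", "F"}
        assert table["M"][0] == 2 and table["F"][0] == 2

    def test_absent_exposure_flag_omitted(self):
        pop = [
            (TLProfile("s1", np.full(10, 8000.0)), _record(1, flags=["pesticides"])),
            (TLProfile("s2", np.full(10, 7000.0)), _record(2)),
        ]
        table = group_summary(pop, by="exposure")
        assert set(table) == {"pesticides", "none"}

    def test_group_medians_match_brute_force(self, rng):
        pop = []
        pooled = {"M": [], "F": []}
        for i in range(1, 9):
            sex = "M" if i % 2 else "F"
            v = rng.uniform(4000, 12000, 40)
            pooled[sex].extend(v)
            pop.append((TLProfile(f"s{i}", v), _record(i, sex)))
        table = group_summary(pop, by="sex")
        for sex in ("M", "F"):
            assert table[sex][1].median == pytest.approx(float(np.median(pooled[sex])))

    def test_unknown_grouping_key(self):
        with pytest.raises(ConfigError):
            group_summary([], by="shoe_size")
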