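# Methods

## Data model

One Q-FISH examination yields one fluorescence intensity per telomere,
addressed by the tuple *(chromosome 1–23, homolog a/b, metaphase 1–n, arm
end p1/p2/q1/q2)*. With the default ten metaphases the complete grid has
23 × 2 × 4 × 10 = 1840 slots. Readings at or near background fluorescence
arrive coded `ND` and are carried through the pipeline as missing (NaN);
thresholding to ND is the upstream image analyst's decision, so an intensity
of exactly 0 is treated as valid data here. The grid assumes 23 chromosome
"pairs" for every participant; male sex chromosomes are not a true pair, but
no sex-specific grid is applied — the homolog label is an arbitrary a/b tag.

Dates are accepted in ISO-8601 only; day/month-ambiguous forms such as
`12/1/1970` are rejected outright rather than guessed. Chronological age is
decimal years, `(sampling − birth) in days / 365.25` — fractional rather
than integer age because the nomogram needs a continuous axis. Participant
identification codes truncate names to three letters; names shorter than
three letters are right-padded with `_` so the code layout stays fixed.

## Calibration

Both calibration levels are multiplicative scalars, so their order is
irrelevant (a property test asserts the commutation to 1e−12 relative):

1. **Bead correction** for daily lamp/alignment drift: each intensity is
   multiplied by `reference_intensity / session_intensity` of fluorescent
   beads imaged before the session.
2. **Standard conversion** to physical units through a cell line of stable,
   known telomere length (L5178Y-S, ≈7 kb): a zero-intercept linear map
   `TL_kb = known_tl_kb · I / I_standard_mean`. The proportionality through
   the standard's operating point is the simplest model consistent with
   intensity ∝ length; `known_tl_kb` defaults to 7.0 but is configurable
   because the standard's length is itself an estimate. Per-session
   standards may override the global one for slide-level normalization.

Internal storage is bases (1000 × kb); display is kb with one decimal.
Missing values propagate untouched through both levels.

## Quantile engines

Two quartile definitions are implemented side by side because they are the
two a practitioner will meet when cross-checking results between a
spreadsheet and a classic statistics package:

- **Inclusive linear interpolation** (spreadsheet `PERCENTILE`, quantile
  type 7): rank `h = 1 + (n−1)·p/100` on the sorted sample, linear
  interpolation between the bracketing order statistics. The inclusive
  variant is used because the 0–100 grid requires defined values at p=0 and
  p=100 (the exclusive variant is undefined there).
- **Tukey's hinges** (fivenum): fold the sample at the median; each half
  includes the median element when n is odd, and the hinges are the medians
  of the halves.

Both engines reduce to the standard sample median, so medians agree
*exactly* on every dataset while Q1/Q3 can differ by a fraction of a step —
this mechanism is asserted bit-exactly in the tests (the even-n median is
computed with the identical lerp expression in both engines so no last-ulp
difference survives). The hinge implementation is verified against an
independent formulation, the hinge-depth rule `d = (⌊(n+1)/2⌋+1)/2`; the
linear engine against numpy's type-7 quantile.

## Short and extreme telomeres

The short-telomere subset (TLS) of a sample keeps values **strictly** above
the sample minimum and **strictly** below the 20th percentile. Ties at
either bound are excluded, so the subset always holds < 20% of the values;
TLS summary statistics are the ordinary descriptive summary applied to the
subset. Extreme counts use strict thresholds of 3 kb (extremely short) and
20 kb (extremely long), both configurable.

Histograms bin TL into fixed-width intervals (default 0.5 kb) with
*inclusive upper* edges `(prev, upper]` — the convention of spreadsheet
`FREQUENCY`-style upper limits — with 0 assigned to the first bin. The bins
containing the median and the 20th percentile are reported so charts can
highlight them.

## Nomograms and biological age

Individuals are binned into age groups (decadal 20–90 by default,
configurable); within each group the members' calibrated TL values are
pooled and reduced to percentile levels 10, 25, 50, 75, 90, 95 with the
linear engine. Each level is fitted with ordinary least squares against the
age-group midpoint, giving intercept *a* (bases), slope *b* (bases/year) and
R². Zero-variance (flat) levels report R² = 1 with a `degenerate` flag so
flat fixtures don't crash reporting. The TLS nomogram is built the same way
from each member's short-telomere subset.

Biological age for an individual with median TL *m* at chronological age
*t*:

1. compare *m* with the P50 curve interpolated at *t* (above/below median);
2. select the percentile curve with the smallest vertical distance
   |m − curve(t)|, ties broken toward the lower level — "nearest" considers
   **all** curves, not only the two bracketing ones (an interpretation;
   both choices coincide except at extreme values);
3. invert the selected level's fitted line: `bio_age = (m − a)/b`, defined
   only for declining lines (b < 0);
4. clamp to the nomogram age range ±10 years.

A median below the population median curve is interpreted as biological age
above chronological age. The nearest-line inversion can contradict this
near curve crossovers; the contradiction sets a warning flag rather than
raising, because the data model does not resolve which signal should win.
Note the estimate is only piecewise monotone in *m*: within one nearest-line
basin it decreases strictly with increasing median TL, but switching to a
different reference line re-anchors the inversion, so small jumps at basin
boundaries are expected and documented rather than suppressed.

Group pivot summaries (by age group, sex or exposure flag) pool the member
values per group and report the full descriptive summary with group counts;
empty groups are omitted. Sex is not a default stratification axis for the
nomogram — TL percentiles are not strongly sex-dependent at these cohort
sizes — but sex grouping is available in the pivot.

## Longitudinal rates

For repeat measurements of one individual, consecutive pairwise rates are
`Δstatistic / Δyears` (years via /365.25), on the median by default (any
summary field is selectable). With ≥3 points an overall least-squares slope
is also emitted. Only summary statistics are compared across visits; no
within-individual measurement-error model is attempted.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
the imaging process. Per-slot telomere length (kb) is log-normal — right-
skewed and positive, matching the shape of observed per-telomere
distributions — with arithmetic mean

```
mean_kb(age) = mean_tl_at_20_kb + decline_kb_per_year · (age − 20)
```

floored at 0.5 kb, and a fixed per-telomere coefficient of variation.
Defaults: 9.0 kb at age 20, −0.04 kb/year, CV 0.35, ND dropout 2%, ten
metaphases. Emitted intensities sit on the default calibration standard's
scale (`I = TL_kb/7 × 100 AU`), so calibration inverts the simulation
exactly and round-trip tests are sharp to 1e−9. Cohorts draw ages uniformly
on 21–82 years with a 52.3% male fraction, mirroring a typical adult
reference population; demographics (synthetic names, codes, back-computed
birth dates from a fixed 2018-06-15 sampling date) are deterministic under
the seed. An optional 23-vector of per-chromosome offsets exists for testing
per-chromosome reports; by default no chromosome structure is simulated.

What passing tests on these data do **not** show: robustness to imaging
artifacts, background-fluorescence misclassification, metaphase quality
variation, chromosome-specific telomere biology, or non-uniform real age
structures. The log-normal CV is homogeneous across individuals, which real
cohorts are not.

## Numerical and scale choices

- Percentile level p and the grid are on the 0–100 scale; levels outside it
  are domain errors, empty samples are domain errors everywhere.
- The slope-recovery check regresses per-individual medians on age for 60
  individuals × 2 metaphases × 10 replicate seeds and requires the fitted
  slope within ±20% of the generator's decline; the log-normal median is
  `mean/√(1+cv²)` ≈ 0.94 × mean, a bias well inside that band. These sizes
  keep the full suite under half a minute while leaving ≈6σ of margin on
  the recovery bound.
- Histogram cumulative frequencies are forced to end at exactly 1 to absorb
  float round-off in the final bin.
- Report text renders kb, percentages and ages with one decimal, always
  formatted from the same values the JSON sidecar carries.

## Known limitations

- No confidence intervals on percentiles or on the biological-age estimate.
- Nomogram fits are linear only; no spline/exponential alternatives.
- The biological-age estimate is a crude point estimate on a reference
  cohort; it inherits every bias of that cohort and of the nearest-line
  interpretation.
- The measurement grid ignores sex-chromosome copy number in males.
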