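# Methods

## The model and its assumptions

`cantrend` implements a ratio nowcaster: next year's case count in a
region is this year's count scaled by the year-over-year change in the
region's relative search volume index (RSVI) for the disease topic,

    predicted(t+1) = cases(t) * RSVI(t+1) / RSVI(t).

The model assumes that public search interest is (approximately)
proportional to incidence within a region, so that the *ratio* of
successive index values tracks the ratio of successive counts. It makes
no use of age, period or cohort structure — it is a one-parameter-free
rescaling, attractive precisely because registry counts arrive years
late while search indices are available immediately. The assumption is
fragile in the ways one would expect: attention shocks (a celebrity
diagnosis, a competing health crisis) move search interest without
moving incidence, and the index is normalized within the query window,
so its absolute level carries no information — only ratios are used
anywhere in the package.

Validation uses the signed percentage error
`%error = (predicted - actual) / actual * 100`, undefined for
non-positive actuals.

## Precision and rounding conventions

All model arithmetic is full double precision; rounding is display
only. The conventions, fixed once and applied everywhere:

- **Predicted counts** round to integers half-away-from-zero
  (`round_count`). The reference tables are only reproducible with the
  *full-precision* ratio: e.g. 27,550 × 86/89 = 26,621.35 → 26,621,
  while the 3-decimal display ratio 0.966 would give 26,613.
- **Ratios** display at 3 decimals, **%errors** at 1 decimal, both
  half-away-from-zero (implemented with `decimal` to avoid binary
  double surprises). A printed ratio of 1.089 arising from 1.0889
  fixes rounding-to-nearest rather than truncation; no reference cell
  distinguishes tie behaviour, so half-away-from-zero is fixed and
  documented rather than inferred.
- **%error inside a prediction record is computed from the unrounded
  prediction**, not the rounded count. The packaged 2017 table itself
  fixes this convention: North Dakota's printed −1.6 matches the raw
  prediction 3,921.27 (−1.648) but not the rounded 3,921 (−1.655).
  The standalone `percent_error(predicted, actual)` stays generic.
- **Chained forecasts carry unrounded values between steps**, so the
  k-step forecast telescopes exactly to the combined-ratio one-step
  form; rounding happens once, at reporting.

An RSVI of 0 means *insufficient search data*, not zero interest; it is
an error (`InsufficientSearchDataError`), never a zero forecast.
Missing years are never interpolated: the ratio is defined only on
consecutive observed years, and a chained forecast refuses to run if any
year in its span lacks a positive index, naming the first offending
year.

## Input conventions

- Region keys are USPS two-letter codes for US states (DC included) and
  ISO-3166-1 alpha-2 codes for countries; display names in inputs and
  fixtures are normalized to codes, with the original string retained
  in the fixture tables. Stable short keys make region joins (model
  comparison, map exports) unambiguous.
- Yearly RSVI from a monthly multiTimeline export is the arithmetic
  mean of the 12 monthly values, kept at full precision. The upstream
  aggregation used to produce published yearly values is not specified
  anywhere; the mean is the simplest defensible convention and is
  isolated in one function so it can be swapped. Years with fewer than
  12 months are excluded with a warning. `<1` cells parse as 0.5, the
  midpoint of the interval they denote — any constant in (0, 1) would
  do, and 0.5 keeps them distinct from true 0.
- Multi-year validation re-bases every year on the *previous year's
  actual*, never on the previous prediction; chaining is reserved for
  years with no actuals. Each printed %error in the packaged 2018–2020
  table matches its own printed predicted/actual pair, confirming the
  tables were built the same way.
- Regions that cannot be scored (missing actual, missing index) are
  returned in a `skipped` mapping with a reason, never silently
  dropped.

## Packaged reference tables

Four CSV fixtures hold the published validation tables, transcribed
cell-for-cell (Unicode minus normalized to ASCII; %error cells stored
exactly as printed at 1 decimal, separate from recomputed
full-precision errors). Points of note, all asserted by tests:

- The 2017 table titled for fifty states actually lists 49 states plus
  DC — Kansas is absent. The fixtures transcribe what is printed; the
  validation machinery reports skips rather than imputing.
- The 2017 %error column has arithmetic mean −0.98 and median −1.55.
  The published summary calls −0.98 a "median"; it is numerically the
  mean of the printed column. `ErrorSummary` therefore always reports
  *both* statistics, explicitly labelled, so the discrepancy is visible
  rather than silently resolved.
- 149 of the 150 %error cells of the 2018–2020 table are exactly
  consistent with their printed predicted/actual pairs at 1-decimal
  rounding. The exception is Rhode Island 2018 (printed 1.7; the
  printed integers give 1.646 → 1.6), explained by the source rounding
  its unrounded prediction (≈6,669.27 → 1.6503 → 1.7); the unrounded
  value is unrecoverable because the 2018 index values were never
  published. The consistency test asserts all 150 cells and therefore
  fails on this one cell by design: it documents the table exactly as
  printed.
- The 2021–2023 projections (US states and 54 countries) print outputs
  only — their RSVI inputs were never published — so those fixtures are
  reference values, and only the chaining *mechanism* (unrounded
  carries, telescoping, predicted-provenance flags) is tested.

A sha256 checksum test freezes all four files, and an arithmetic
integrity test rederives every derivable 2017 cell (ratio, predicted
count, %error) from the independent input cells, so any transcription
slip in either group of columns would surface as an inconsistency.

## Synthetic generator

The generator emulates the coupling premise on which the model rests.
Per region r and year t:

    incidence[r,t] = incidence[r,t-1] * exp(trend_r + eps[r,t]),  eps ~ N(0, incidence_noise_sd²)
    rsvi_raw[r,t]  = incidence[r,t]^gamma * exp(eta[r,t]),        eta ~ N(0, rsvi_noise_sd²)

with each region's index rescaled so its window maximum is 100
(mirroring how a trends service normalizes within a query window) and,
by default, rounded to integers with floor 1 to emulate the published
0–100 integer scale. Noise is multiplicative log-normal because both
quantities are positive and the estimator is a ratio, making its error
scale-free. The eps and eta streams are spawned independently from the
master seed, so zeroing one does not shift the other.

Defaults emulate US-state-scale registries: 50 regions, years
2016–2020, base counts 3,000–180,000 (the observed state range), 1 %
mean annual drift with 2 % between-region spread, 2 % incidence noise,
proportional coupling (gamma = 1), 5 % index noise, integer scaling.

What the generator shows — and does not. In the exact-coupling limit
(gamma = 1, no noise, continuous index) the model's %error vanishes up
to IEEE rounding (observed ≲ 1e-13; asserted < 1e-9 — exact floating
zero is not attainable because the rescaled ratio incurs last-ulp
rounding). With integer scaling, quantization perturbs each ratio term
by ≤ 0.5, bounding |%error| near 1 % when the index sits near 100.
Median |%error| grows monotonically with index noise.

One property worth stating explicitly: under *perfect proportional*
coupling with i.i.d. index noise, chained error does **not** compound —
telescoping cancels every interior year, leaving only the endpoint
noises, so the k-step error distribution is flat in k. Error compounds
with horizon when the coupling is imperfect and incidence drifts (e.g.
gamma < 1 with a positive trend gives a bias ≈ (1−gamma)·trend per
step), which is the regime the horizon-compounding test exercises. The
generator deliberately does not model attention-displacement shocks
(interest switching to a competing topic while incidence continues);
a coupling break of that kind is an extension point, not a tested
scenario. Passing tests on this generator therefore certify the
estimator's arithmetic and its behaviour under stationary multiplicative
noise — not robustness to real-world attention shocks, reporting
artifacts, or registry revisions.

## Numerical choices

- Telescoping, ratio-inversion and zero-noise assertions use 1e-9
  relative tolerance; record-internal consistency checks use 1e-12.
- `ErrorSummary` validates mean/median ∈ [min, max] with 1-ulp-scale
  slack (a float mean of identical values can exceed the maximum by one
  ulp).
- Median uses the midpoint convention for even n.
- Degenerate inputs fail loudly: empty error vectors, non-positive
  actuals, negative counts, horizon < 1, out-of-scale indices, and
  overwriting an actual count with a predicted one are all errors.

## Problem sizes

The test suite and the acceptance script run at the scale of the
published tables (50 regions × 4 years) and modest synthetic scales
(up to 200 regions × 5 years; 1,000 random vectors for the summary
oracle); the full suite completes in a few seconds.

## Known limitations

- The model is short-term by construction; it has no mechanism for
  multi-year structural change and no uncertainty quantification (the
  source provides none).
- Published chained projections for 2021–2023 cannot be verified even
  in principle without their unpublished index inputs.
- Whether published yearly index values came from the topic entity or
  the literal search term, and how months were aggregated, is unknown;
  the readers accept both pre-aggregated yearly values and raw monthly
  exports so either interpretation can be fed in.
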