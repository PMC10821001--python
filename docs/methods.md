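# Methods

## Conversion model

The package estimates the effective dose (ED, mSv) of a pediatric brain
CT examination as the product of the scanner-reported dose–length
product (DLP, mGy·cm) and an age-dependent conversion factor
(mSv·mGy⁻¹·cm⁻¹). The ICRP anchor factors bundled for the brain are
0.011, 0.0067, 0.0040 and 0.0032 at 0, 1, 5 and 10 years; any other
anchor table with strictly increasing ages and positive factors can be
supplied.

Four ways of extending the anchors to arbitrary pediatric ages are
implemented:

1. **Curve method.** The shifted power law `y = a (x + b)^c` is fitted
   through the anchors by *unweighted* nonlinear least squares (no log
   transform, no weights). The form is empirical: it is the simplest
   smooth three-parameter family that reproduces the anchors' rapid
   early fall and slow late fall. The constraint `b > 0` keeps the
   model defined at age 0; a decreasing curve has `c < 0`.
2. **Linear method.** Piecewise-linear interpolation between bracketing
   anchors; beyond the oldest anchor, linear extrapolation of the last
   two anchors. Reproduces anchor values exactly.
3. **Simple method.** The anchor factor of the nearest anchor age,
   defined on integer ages only, with equidistant ties resolved toward
   the older anchor. For the brain anchors this yields the mapping
   0 → 0 y, 1–2 → 1 y, 3–7 → 5 y, 8–14 → 10 y.
4. **Phantom-bin method.** A piecewise-constant ED/DLP ratio per age
   bin, emulating Monte-Carlo dose-management systems that select a
   computational phantom by age. Bundled brain bins: 0–0.5, 0.5–2.5,
   2.5–7.5, 7.5–12.5, 12.5–15 years with ratios 0.0115, 0.0076, 0.0047,
   0.0036, 0.0028. Bins are half-open `[lower, upper)`; the last bin is
   closed at 15. The sub-year edges mean this method is always
   evaluated at the actual decimal age.

Relative conversion factors (method ÷ curve) quantify how far each
comparator departs from the smooth curve; they are kept at full
precision internally and rounded to two decimals only for display.

## Fitting

Four points and three parameters make the SSR surface flat and
banana-shaped in (b, c), so a single local search is unreliable. The
fitter profiles the scale in closed form — for fixed (b, c) the optimal
scale is `a = Σyᵢgᵢ / Σgᵢ²` with `gᵢ = (xᵢ + b)^c` — over a coarse
24 × 24 grid spanning b ∈ [0.02, 5] (geometric) and c ∈ [−2, −0.05],
then refines the eight lowest-SSR cells with Levenberg–Marquardt
(tolerances 10⁻¹² on the relative SSR change, 10⁻¹⁵ on steps) and keeps
the lowest minimum. The test suite verifies that this agrees with an
independent brute-force profile-grid oracle to 10⁻⁵ per parameter on
the brain anchors and on randomly generated anchor sets, and that the
result is independent of any user-supplied starting triple.

The fit to the bundled brain anchors gives

    y = 0.007460 (x + 0.3462)^−0.3662

with residual standard deviation `sqrt(SSR / (n − p))` =
`sqrt(SSR / 1)` = 0.00005 (the divisor convention — residual degrees of
freedom, n = 4 anchors, p = 3 parameters — is a deliberate, documented
choice; nothing in the data dictates it). The curve passes within
4 × 10⁻⁵ of every anchor, i.e. within one residual SD of three anchors
and well inside 3 SD of all four.

Reported fit diagnostics: residuals are *model minus anchor* at each
anchor age, and `converged` reflects the optimizer status of the best
start.

## Age conventions

Survey analyses are run on integer ages: the integer age is the floor
of the decimal age (2 years 6 months → 2). Batch conversion evaluates
curve and linear factors at the integer age by default; a
continuous-age switch uses the decimal age instead, which is the right
choice for scatter-style analyses. The curve changes steeply below 1
year, where its validity between the 0- and 1-year anchors cannot be
checked against anything; results for records under 1 year therefore
carry a caution flag, and within-first-year ED *changes* should not be
read off the curve.

Ages at or above 15 years are outside every bundled binning scheme and
are rejected by the summarizers.

## Cohort summaries

Quantities (DLP, per-method ED, device ED/DLP ratio) are summarized per
bin of one of three schemes: integer years (15 bins), DRL age groups
(0, 1–4, 5–9, 10–14), or the phantom bins. Integer-year and DRL bins
assign on the floored integer age; phantom bins on the decimal age.
Conventions, chosen as standard survey practice since none is forced by
the data: the median of an even-sized group is the mean of the two
central order statistics; SD uses the n−1 divisor; CV = 100·SD/mean
(%); a single-record bin reports SD = CV = 0; empty bins are emitted
with n = 0 and NaN statistics so per-age profiles over 0–14 are always
complete. Records lacking a device ED are excluded from device-channel
statistics (a marked absence, never imputed zero).

## Synthetic cohorts

The generator produces examination records with the statistical
structure the analysis assumes, so the pipeline is testable end to end
without patient data.

* **Ages.** A configured count per integer year (default 65–66 per
  year, 980 total — a realistic single-center multi-year volume), drawn
  uniformly within each year.
* **DLP.** Mean DLP(age) = `d_sat − (d_sat − d0)·exp(−rate·age) +
  slope·age`, defaults d0 = 300, d_sat = 575 mGy·cm, rate = 1.1 /yr,
  slope = 20 mGy·cm/yr: a fast first-year rise (head growth under
  automatic exposure control, ≈ +200 mGy·cm in year one) on top of slow
  sustained growth through adolescence (≈ +20 mGy·cm/yr). A pure
  saturating exponential was rejected because it flattens completely by
  mid-childhood, which real AEC-modulated head-CT series do not do, and
  because a flat mean makes per-age sample medians order randomly. The
  defaults are chosen so that adjacent-age differences in the mean
  (≥ 20 mGy·cm) exceed roughly 2.5 standard errors of a per-age sample
  median at the default cohort size — the age trend, not sampling
  noise, is what downstream assertions exercise. Absolute levels are
  plausible for pediatric head CT but are fixtures, not measurements.
* **Noise.** Multiplicative lognormal with unit mean on both DLP and
  device ED (positivity, scale-free CV). Defaults: CV 3% for DLP and 3%
  for the device channel, the latter matching the ≤ 4.4% per-bin ratio
  CV observed for a real Monte-Carlo dose-management system.
* **Device ED.** Phantom-bin ratio at the record's decimal age × DLP ×
  noise, so in the noiseless limit the device ED/DLP ratio is exactly
  piecewise constant with jumps only at bin edges.
* **Reproducibility.** All draws come from one `numpy` generator seeded
  from the config; identical config ⇒ identical cohort.

What the generator does **not** emulate — and what passing pipeline
tests therefore do not establish about real data: realistic
patient-to-patient DLP dispersion (real head-CT series have CVs several
times larger, from scan-length, habitus and protocol variation),
sex-specific growth, scanner or protocol mix, re-scan correlation
within patients, and any physical AEC model. The generator's role is to
realize the qualitative age structure (rising DLP, falling-then-flat
curve-method ED, the simple method's saw-tooth, the device channel's
piecewise-constant ratio) at realistic sample sizes.

## Numerical and degenerate-input choices

* Fewer than 4 anchors → explicit under-determined-fit error; a
  3-anchor table would be an exact interpolation, not a fit.
* Ages where a bin or anchor range is undefined (below the first
  anchor, outside phantom bins, ≥ 15 years for schemes) raise
  validation errors rather than extrapolating silently.
* DLP = 0 is a valid record (ED = 0) but cannot form an ED/DLP ratio.
* CSV rows that fail to parse are skipped and reported per row;
  missing required *columns* abort with the column name.
* File outputs are byte-deterministic given config and seed; run
  manifests (options + seed + version) are written beside outputs.

## Known limitations

* Only brain-CT anchor values and phantom bins are bundled; other body
  regions require a user-supplied anchor table.
* The curve method is an empirical smoother of four tabulated values;
  it carries no organ-dose physics, and its sub-year behaviour is
  unvalidated by construction.
* No CTDIvol handling, DICOM ingestion, DRL percentile aggregation
  across facilities, or hypothesis testing.
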