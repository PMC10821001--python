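# dosecurve

Age-dependent conversion of the dose–length product (DLP) to effective
dose (ED) in pediatric brain CT.

## The problem

CT scanners report the DLP (mGy·cm); the risk-relevant quantity for dose
management and communication is the effective dose (mSv), usually
estimated as

    ED = DLP × k(age)

with a body-region- and age-specific conversion factor *k*
(mSv·mGy⁻¹·cm⁻¹). The ICRP publishes pediatric brain-CT factors only at
0, 1, 5 and 10 years (0.011, 0.0067, 0.0040, 0.0032), so every cohort
analysis must decide how to convert at the other ages. As children grow,
automatic exposure control raises the DLP while *k* falls — the two
trends pull the ED in opposite directions, and the choice of conversion
method changes the apparent ED-versus-age profile.

`dosecurve` implements and compares four conversion methods:

* **curve method** — fit the shifted power law `k(x) = a (x + b)^c`
  through the four anchors by unweighted nonlinear least squares and
  evaluate it at any age (`b > 0` keeps the curve defined at birth,
  `c < 0` makes it decrease);
* **linear method** — piecewise-linear interpolation between anchors,
  linear extrapolation beyond 10 years from the 5- and 10-year anchors;
* **simple method** — the anchor factor of the nearest anchor age (ties
  to the older anchor), i.e. 0 → 0 y, 1–2 → 1 y, 3–7 → 5 y, 8–14 → 10 y;
* **phantom-bin method** — a piecewise-constant ED/DLP ratio per age bin
  (0–0.5, 0.5–2.5, 2.5–7.5, 7.5–12.5, 12.5–15 years), emulating
  radiation-dose-management systems whose Monte-Carlo engine switches
  computational phantoms by age.

It is aimed at medical physicists and dose-survey analysts working with
per-examination dose-record tables (CSV), and ships a seeded synthetic
cohort generator so the whole pipeline is testable without patient data.

## Worked example

Fit the curve and tabulate all methods over integer ages 0–14:

```
$ dosecurve fit
Fitted curve: y = 0.007460 (x + 0.3462)^-0.3662
  a = 0.00745966   |b| = 0.346204   c = -0.366232
  converged: True   n = 4, p = 3
  anchor    0 y: 0.011  residual +9.47e-07
  anchor    1 y: 0.0067  residual -9.87e-06
  anchor    5 y: 0.004  residual +3.72e-05
  anchor   10 y: 0.0032  residual -2.99e-05
  residual SD = sqrt(SSR/(n-p)) = 0.00005

 age   curve  linear  simple rel_linear rel_simple  phantom_bin
   0 0.01100 0.01100 0.01100       1.00       1.00      0.01150
   1 0.00669 0.00670 0.00670       1.00       1.00      0.00760
   2 0.00546 0.00602 0.00670       1.10       1.23      0.00760
   3 0.00479 0.00535 0.00400       1.12       0.83      0.00470
   ...
  14 0.00281 0.00256 0.00320       0.91       1.14      0.00280
```

The fitted curve passes within 4 × 10⁻⁵ of every ICRP anchor (residual
SD 0.00005). The relative-factor columns expose the comparators'
artifacts: the simple method applies the 1-year factor to 2-year-olds
(23% above the curve, `rel_simple` 1.23) and the 5-year factor to
3-year-olds (17% below, 0.83); the linear method overshoots around 2–4
years and undershoots beyond 12.

Simulate a 980-examination cohort and summarize it by DRL age group:

```
$ dosecurve simulate --seed 7 --out cohort.csv
980 record(s) written to cohort.csv (seed 7)
$ dosecurve summarize cohort.csv --scheme drl_group --out summary.csv
== dlp ==
  bin   n  median  mean    sd  cv_percent
    0  65   423.8 414.5 56.87       13.72
  1-4 260   619.2 612.5 47.37       7.734
  5-9 325   722.2 725.7 37.98       5.234
10-14 330   824.1 825.9 37.33        4.52
== ed_curve ==
  bin   n  median  mean      sd  cv_percent
    0  65   4.663 4.559  0.6256       13.72
  1-4 260   3.171 3.224  0.3206       9.943
  5-9 325   2.608 2.625  0.1183       4.505
10-14 330   2.456 2.459 0.07909       3.217
...
```

Median DLP rises with age (head growth under automatic exposure
control) while the curve-method median ED falls from 4.7 mSv in the
0-year group to 2.5 mSv in the 10–14-year group and flattens — the
falling conversion factor first outweighs, then balances, the rising
DLP. `dosecurve convert records.csv --out out.csv` augments a record
table with per-method factor and ED columns; `--continuous-age`
evaluates the curve at the decimal age instead of the floored integer
age.

The same functionality is available as a library
(`dosecurve.fit_power_law`, `curve_factor`, `convert_records`,
`summarize`, `generate_cohort`, ...).

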