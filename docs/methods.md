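# Methods

## Model

All statistics derive from linear regression of observed values y on
calculated values x, `y = a + b·x`, under three nested constraint schemes:

* **VAL** — a = 0, b = 1 fixed. No parameters are estimated; the residuals
  are y − x about the identity line.
* **BIAS** — b = 1 fixed, a estimated. The least-squares intercept at unit
  slope has the closed form a = mean(y − x); a is reported as the *bias*
  of the prediction, in log units.
* **PEARSON** — a and b estimated by ordinary least squares (closed form
  b = S_xy/S_xx, a = ȳ − b·x̄); b is reported as the *slope* (tilt).

For each fit, r² = 1 − SS_res/SS_tot where SS_res is the residual sum of
squares about that fit's line and SS_tot = Σ(y − ȳ)² is always taken about
the mean observed value. Using one common SS_tot is what makes the three
r² comparable, and what allows r²_val and r²_bias to go negative for
models whose residuals exceed the spread of the data; negative values are
reported as-is, never clamped. RMSE = √(SS_res/d) with the denominator d
set by a convention (below).

Nesting of the constraint sets gives, for any dataset,
SS_res(PEARSON) ≤ SS_res(BIAS) ≤ SS_res(VAL), hence
r²_Pearson ≥ r²_bias ≥ r²_val and, under a common denominator,
RMSE_Pearson ≤ RMSE_bias ≤ RMSE_val. Two exact identities follow from the
closed forms and hold to machine precision:

* r²_Pearson equals the square of the product-moment correlation
  r = Σ(x−x̄)(y−ȳ)/√(Σ(x−x̄)²·Σ(y−ȳ)²);
* Σ(y−x)² = Σ(y−x−ā)² + n·ā² with ā = mean(y−x), i.e.
  RMSE_val² = RMSE_bias² + bias² under the denominator-n convention —
  the identity-line error decomposes exactly into scatter plus offset.

### Axis convention

Observed values are the dependent variable (y-axis), calculated values the
independent variable (x-axis). This is fixed and non-configurable. Because
regression of y on x and of x on y give different lines, swapping the axes
silently changes every non-VAL statistic; the file readers therefore select
columns strictly by name, with no positional fallback.

### RMSE denominator conventions

Two conventions are offered:

* `"n"` (default): d = n for all three families. This is the only choice
  under which the decomposition identity above is exact and the
  cross-family RMSE ordering is guaranteed, so it is the default and the
  convention used for all cross-family comparisons.
* `"see"`: emulates the "standard error of estimate" printed by common
  curve-fitting and plotting software: d = n − 2 for the BIAS and PEARSON
  families, d = n for VAL. Such software specifies the model as y = a + b·x
  with two parameters and uses n − 2 regardless of whether the slope was
  constrained to 1, which is why the BIAS family also gets n − 2 here (not
  the n − 1 a parameter count would suggest). The mode exists so that
  numbers published from those programs can be reproduced and audited; it
  is a compatibility surface, not the recommended statistic.

## Parameters that matter

| parameter | units | default | why |
|---|---|---|---|
| minimum n | pairs | 3 | the unconstrained fit spends 2 degrees of freedom; fewer than 3 pairs makes any fit vacuous |
| `dof_convention` | — | `"n"` | see above |
| `gap_threshold` (diagnose) | r² units | 0.05 | heuristic: gaps well above what sampling noise produces at typical n (hundreds) and noise levels (±0.2–0.6 log); configurable, not a published cutoff |

## Synthetic-data generator

Each pair starts from a latent true value t ~ Uniform(x_range). The
observed value is t + e with e symmetric random noise; the per-point
half-width h is drawn uniformly from `noise_half_width_range`, and by
default e ~ Uniform(−h, h), so every injected error is bounded by the
largest half-width — the "±h" is literal and testable. A Gaussian
alternative (e ~ N(0, h²)) is available behind the `noise` flag for
heavier tails. The calculated value is x = (t − bias)/tilt: systematic
error is placed in the *calculated* column because it originates in the
limitations of the prediction model, while the measurement carries only
random error. By construction y ≈ bias + tilt·x, so the unconstrained
regression recovers intercept ≈ bias and slope ≈ tilt at large n.

Defaults: x_range = (−7, −1) log₁₀ mol/L, spanning typical druglike
intrinsic solubilities from practically insoluble to freely soluble;
noise half-widths 0.24–0.57 log units, the scale of careful solubility
measurement reproducibility. Four canonical presets (n = 5000, fixed
seeds) cover the regimes: `clean` (bias 0, tilt 1), `bias_only`
(bias −0.6), `tilt_only` (tilt 0.7), `bias_and_tilt` (bias 0.4, tilt 0.7).

What the generator does **not** emulate: real solubility data have
non-uniform value distributions, heteroscedastic and occasionally
asymmetric measurement error, curvature (model error that is not an affine
map), and outliers. Tests passing on this generator demonstrate the
correctness of the statistics and the estimators under affine systematic
error with bounded symmetric noise — not robustness to those real-data
features.

A note on the `tilt_only` preset: a slope distortion across an off-origin
range (mean ≈ −4) also shifts the mean of the calculated values, so the
unit-slope fit absorbs part of the tilt as an apparent offset and the
diagnostic legitimately reports `bias_and_tilt`. Only a tilt about a
zero-centered range leaves the bias gap closed; this is a property of the
statistics, not an artifact of the generator.

## Diagnosis

`diagnose` reads the two r² gaps: r²_bias − r²_val responds to a constant
offset, r²_Pearson − r²_bias to a slope distortion. A gap above
`gap_threshold` flags the corresponding error, yielding labels `none`,
`bias`, `tilt`, `bias_and_tilt`. The rule is monotone in the threshold:
raising it can only weaken the diagnosis.

## Numerical choices and degenerate inputs

* All sums of squares are computed in double precision from mean-centered
  columns; the Pearson correlation is clipped to [−1, 1] only against
  floating-point overshoot.
* Constant observed values (SS_tot = 0) raise an explicit degenerate-data
  error rather than returning ±∞ or NaN; constant calculated values do the
  same for the unconstrained fit and the correlation, naming the offending
  column.
* Batch evaluation never aborts on a bad group: failures are collected and
  reported per group alongside the successful rows.
* Reports print statistics to two decimals (the conventional precision for
  this kind of table); machine-readable CSV output keeps full precision.

## Problem sizes used in the checks

The self-checks run at sizes where sampling noise is well below the
asserted tolerances: 1000 random datasets of 3–500 pairs for the ordering
and identity properties, 20 datasets of ≤ 10 pairs against a brute-force
grid minimizer (refining grid in the orthogonal parametrization, final
resolution ≪ 10⁻³), the clean preset at n = 5000 for the coincidence
limit, and 200 scenarios at n = 2000 for bias/tilt recovery (mean absolute
error ≈ 0.01 for bias, ≈ 0.003 for tilt). The whole suite completes in a
few seconds.

## Known limitations

* Ordinary least squares only: no weighting, no orthogonal (total
  least-squares) regression, no outlier rejection. All error is attributed
  to y given x.
* The diagnostic threshold is a heuristic on r² gaps; at very small n or
  very high noise the gaps fluctuate and labels should be read with the
  sampling variability in mind.
* The package scores predictions; it contains no solubility models.
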