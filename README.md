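# predval

Validation statistics for observed-vs-calculated prediction scatter plots,
built for the QC step that follows any physical-property prediction run —
the motivating case is aqueous intrinsic solubility (log S₀) prediction in
drug discovery, but any paired observed/predicted data on a common scale
works.

## The problem

When a prediction model is scored against measurements, "r²" and "RMSE" are
not single numbers: their values depend on which line the residuals are
taken about. Different software silently uses different conventions, so
models compared across publications can look better or worse than they are.
With observed values y on the vertical axis and calculated values x on the
horizontal axis, three nested least-squares fits of y = a + b·x define
three statistic families:

| family | constraint | what it measures |
|---|---|---|
| **val** | a = 0, b = 1 (identity line) | absolute predictive agreement |
| **bias** | b = 1, a fitted (a = mean(y − x)) | agreement forgiving a constant offset ("bias") |
| **Pearson** | a, b fitted (ordinary least squares) | agreement forgiving offset and slope distortion ("tilt") |

Each family gets r² = 1 − SS_res/SS_tot (SS_tot always about the mean
observed value) and RMSE = √(SS_res/n). Because the fits are nested,

```
r²_Pearson ≥ r²_bias ≥ r²_val      RMSE_Pearson ≤ RMSE_bias ≤ RMSE_val
```

with equality when the predictions carry no systematic error. The gaps
between the families therefore *diagnose* the systematic error: a bias
opens the first gap, a tilt opens the second. r²_val and r²_bias can be
negative for poor models and are reported as-is. Exact identities the
package maintains: r²_Pearson = r_Pearson² and
RMSE_val² = RMSE_bias² + bias².

The package provides the statistics (`predval.core`), a seedable simulator
of the random-error / bias / tilt regimes (`predval.simulate`), batch
reports with a systematic-error flag (`predval.report`), CSV/TSV readers
(`predval.io`), and a `predval` command-line tool.

## Worked example

Simulate a dataset whose predictions carry a constant −0.6 log-unit offset
and random measurement error of ±(0.24–0.57) log units, then score it:

```sh
$ predval simulate --preset bias_only --n 5000 -o demo.csv
wrote 5000 pairs to demo.csv
$ predval eval demo.csv
group    n  r2_pearson  r2_bias  r2_val  rmse_pearson  rmse_bias  rmse_val  bias  slope
    - 5000        0.98     0.98    0.87          0.24       0.24      0.64 -0.60   1.00
$ predval diagnose demo.csv
bias
```

Reading the row: the Pearson and bias-compensated statistics agree
(r² ≈ 0.98, RMSE ≈ 0.24 — essentially the random measurement error), while
the identity-line statistics are markedly worse (r²_val = 0.87,
RMSE_val = 0.64). That gap is exactly the fingerprint of a constant offset,
and the fitted bias column recovers the injected −0.60. `diagnose` flags
the regime accordingly. The same API is available in Python:

```python
from predval import read_pairs, evaluate
rep = evaluate(read_pairs("demo.csv"))
print(rep.bias, rep.slope, rep.r2_val)   # -0.5993  0.9998  0.8660
```

For real data, point the reader at your own columns:

```sh
predval eval mymodel.csv --observed-col logS0_obs --calculated-col logS0_calc
predval batch mymodel.csv --group-col series --format csv -o stats.csv
```

Note the fixed axis convention: observed values are always the dependent
variable (y), calculated values the independent variable (x); columns are
selected by name, never by position, because swapped axes silently change
every fitted-line statistic.

An RMSE compatibility option (`--dof see`) reproduces the
"standard error of estimate" printed by curve-fitting software, which
divides by n − 2 for any fitted line; the default divides by n for all
three families. See `docs/methods.md` for why.

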