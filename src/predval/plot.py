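"""Optional scatter-plot helper (requires matplotlib)."""

from __future__ import annotations

from .core import ConstraintCase, PairedPredictions, fit_line


def scatter_with_fits(pairs: PairedPredictions, ax=None):
    """Scatter plot of observed vs calculated with the three fitted lines.

    Identity line solid black, unit-slope (bias-compensated) line dashed
    red, unconstrained (Pearson) line dash-dot green — the conventional
    rendering for this comparison.
    """
    import matplotlib.pyplot as plt
    import numpy as np

    if ax is None:
        _, ax = plt.subplots()
    x = pairs.x_calc
    ax.plot(x, pairs.y_obs, "s", ms=4, alpha=0.6, label="data")
    grid = np.linspace(x.min(), x.max(), 2)
    styles = {
        ConstraintCase.VAL: ("k-", "identity (val)"),
        ConstraintCase.BIAS: ("r--", "unit slope (bias)"),
        ConstraintCase.PEARSON: ("g-.", "least squares (Pearson)"),
    }
    for case, (style, label) in styles.items():
        fit = fit_line(pairs, case)
        ax.plot(grid, fit.a + fit.b * grid, style, label=label)
    ax.set_xlabel("calculated")
    ax.set_ylabel("observed")
    ax.legend()
    return ax
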