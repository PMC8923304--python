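import numpy as np
import pytest

from predval import PairedPredictions


@pytest.fixture
def five_pairs() -> PairedPredictions:
    """Small fixed dataset with known least-squares solution."""
    return PairedPredictions(
        y_obs=[0.2, 0.9, 2.3, 2.8, 4.1],
        x_calc=[0.0, 1.0, 2.0, 3.0, 4.0],
    )


@pytest.fixture
def random_pairs_factory():
    """Factory for random scatter datasets with bias/tilt/noise knobs."""

    def make(
        n: int,
        rng: np.random.Generator,
        bias: float = 0.0,
        tilt: float = 1.0,
        noise: float = 0.4,
    ) -> PairedPredictions:
        t = rng.uniform(-7, -1, size=n)
        y = t + rng.normal(0, noise, size=n)
        x = (t - bias) / tilt
        return PairedPredictions(y_obs=y, x_calc=x)

    return make


def grid_search_ols(x, y, c_lo=-20.0, c_hi=20.0, b_lo=-10.0, b_hi=10.0,
                    rounds=6, pts=201):
    """Brute-force minimizer of sum((y - a - b*x)**2) by refining grid search.

    Independent oracle for the unconstrained fit: it only ever evaluates the
    objective on a grid and shrinks the window around the best cell.  The
    search runs in the orthogonal parametrization y = c + b*(x - mean(x)),
    where the objective is separable and the grid argmin is always within
    one cell of the continuous minimum (an uncentered (a, b) grid sits in a
    narrow correlated valley and can refine onto the wrong cell).  The
    intercept is recovered as a = c - b*mean(x).  Final resolution is far
    below 1e-3 on the default window.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    for _ in range(rounds):
        c = np.linspace(c_lo, c_hi, pts)
        b = np.linspace(b_lo, b_hi, pts)
        C, B = np.meshgrid(c, b, indexing="ij")
        resid = y[None, None, :] - C[..., None] - B[..., None] * xc[None, None, :]
        sse = (resid ** 2).sum(axis=-1)
        i, j = np.unravel_index(sse.argmin(), sse.shape)
        dc = (c_hi - c_lo) / (pts - 1)
        db = (b_hi - b_lo) / (pts - 1)
        c_lo, c_hi = c[i] - dc, c[i] + dc
        b_lo, b_hi = b[j] - db, b[j] + db
    return float(c[i] - b[j] * x.mean()), float(b[j])
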