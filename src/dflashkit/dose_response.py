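"""Min/max normalization and four-parameter logistic EC50 estimation.

The response model is the four-parameter log-logistic

    y(x) = floor + (ceiling - floor) / (1 + (ec50 / x)^hill)

so y(ec50) is always the midpoint of floor and ceiling and a negative
Hill slope describes an inhibition (falling) curve with EC50 still
positive. Fitting is ordinary least squares in log-dose space with a
coarse log-spaced EC50 x Hill grid to seed a local refinement, no
weighting, replicate points entering individually.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .synthetic import fourpl

__all__ = ["DoseResponseFit", "minmax_normalise", "fit_4pl",
           "bootstrap_ec50_ci", "fitted_curve"]


@dataclass(frozen=True)
class DoseResponseFit:
    """4PL parameters, fit quality and convergence status."""

    floor: float
    ceiling: float
    hill: float
    ec50: float
    rss: float
    converged: bool
    n_points: int


def minmax_normalise(values, groups=None) -> np.ndarray:
    """Map each group's minimum to 0 and maximum to 1, preserving order.

    ``x' = (x - x_min) / (x_max - x_min)`` within each experiment group
    (one group when ``groups`` is None). A constant group is an error
    naming the group.
    """
    x = np.asarray(values, dtype=float)
    if groups is None:
        groups = np.zeros(x.size)
    g = np.asarray(groups)
    if g.size != x.size:
        raise ValueError("values and groups must align")
    out = np.empty_like(x)
    for key in pd.unique(g):
        sel = g == key
        lo, hi = x[sel].min(), x[sel].max()
        if hi <= lo:
            raise ValueError(f"constant values in group {key!r}: "
                             "min/max normalization undefined")
        out[sel] = (x[sel] - lo) / (hi - lo)
    return out


def _residuals(params, logx, y):
    floor, ceiling, hill, log_ec50 = params
    return fourpl(np.exp(logx), floor, ceiling, hill,
                  math.exp(log_ec50)) - y


def fit_4pl(
    doses,
    responses,
    fix_limits: tuple[float, float] | None = None,
) -> DoseResponseFit:
    """Least-squares four-parameter logistic fit of response on dose.

    Initialization scans EC50 over a log grid spanning the dose range and
    Hill in {+/-0.5, +/-1, +/-2}; the best grid point seeds a
    trust-region refinement parameterized in log(EC50) so the estimate
    stays positive. ``fix_limits=(floor, ceiling)`` pins the asymptotes
    (e.g. (0, 1) after min/max normalization); by default they are free.

    Fewer than 5 distinct doses, or a failed refinement, yields a fit
    flagged ``converged=False`` rather than an exception.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.size != y.size or x.size == 0:
        raise ValueError("doses and responses must align and be non-empty")
    if np.any(x <= 0):
        raise ValueError("doses must be > 0")
    n_distinct = np.unique(x).size
    bad = DoseResponseFit(math.nan, math.nan, math.nan, math.nan,
                          math.nan, False, int(x.size))
    if n_distinct < 5:
        return bad

    logx = np.log(x)
    if fix_limits is not None:
        lo_fix, hi_fix = fix_limits
    grid_ec50 = np.exp(np.linspace(logx.min(), logx.max(), 25))
    grid_hill = (0.5, 1.0, 2.0, -0.5, -1.0, -2.0)
    y_lo, y_hi = float(y.min()), float(y.max())

    best, best_rss = None, math.inf
    for ec50 in grid_ec50:
        for hill in grid_hill:
            if fix_limits is not None:
                floor, ceiling = lo_fix, hi_fix
            else:
                floor, ceiling = y_lo, y_hi
            r = fourpl(x, floor, ceiling, hill, ec50) - y
            rss = float(r @ r)
            if rss < best_rss:
                best_rss = rss
                best = (floor, ceiling, hill, math.log(ec50))

    if fix_limits is None:
        res = least_squares(_residuals, best, args=(logx, y),
                            method="trf", max_nfev=2000)
        floor, ceiling, hill, log_ec50 = res.x
    else:
        def resid2(p):
            return _residuals((lo_fix, hi_fix, p[0], p[1]), logx, y)
        res = least_squares(resid2, best[2:], method="trf", max_nfev=2000)
        floor, ceiling = lo_fix, hi_fix
        hill, log_ec50 = res.x
    rss = float(2.0 * res.cost)
    converged = bool(res.success) and np.isfinite(rss) and rss <= best_rss + 1e-9
    return DoseResponseFit(float(floor), float(ceiling), float(hill),
                           float(math.exp(log_ec50)), rss, converged,
                           int(x.size))


def bootstrap_ec50_ci(
    doses,
    responses,
    n_boot: int = 500,
    seed: int = 0,
    level: float = 0.95,
    fix_limits: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Nonparametric bootstrap percentile CI for the EC50.

    Resamples (dose, response) pairs with replacement ``n_boot`` times
    and refits; returns the percentile interval at the requested level.
    Non-converged resample fits are dropped.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    rng = np.random.default_rng(seed)
    estimates = []
    for _ in range(n_boot):
        idx = rng.integers(0, x.size, x.size)
        fit = fit_4pl(x[idx], y[idx], fix_limits=fix_limits)
        if fit.converged:
            estimates.append(fit.ec50)
    if len(estimates) < max(20, n_boot // 10):
        raise ValueError("too few converged bootstrap fits for a CI")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(estimates, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def fitted_curve(fit: DoseResponseFit, doses) -> pd.DataFrame:
    """Model predictions at the given doses, for plotting/export."""
    x = np.asarray(doses, dtype=float)
    return pd.DataFrame({
        "dose_molar": x,
        "response": fourpl(x, fit.floor, fit.ceiling, fit.hill, fit.ec50),
    })
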