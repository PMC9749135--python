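"""Ordinary least squares with adjusted r-squared, and the hydrology regressions.

The two headline fits supported here relate (a) phytoplankton
photosynthetic efficiency (yield) to the bacteria:archaea distance ratio
T_bac:T_arc, and (b) the seasonal (August - December) difference in the
per-reservoir mean F:T_mic to log10-transformed hydraulic load.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    r2_adj: float
    p: float
    n: int
    conf_level: float
    slope_halfwidth: float
    intercept_halfwidth: float


def linfit(x, y, conf_level: float = 0.95) -> RegressionResult:
    """Closed-form simple OLS of y on x with two-sided slope test.

    Adjusted r2 uses the simple-regression identity
    r2_adj = 1 - (1 - r2)(n - 1)/(n - 2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant: slope undefined")
    xc = x - x.mean()
    sxx = (xc ** 2).sum()
    slope = (xc * (y - y.mean())).sum() / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - (intercept + slope * x)
    sse = (resid ** 2).sum()
    sst = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    dof = n - 2
    sigma2 = sse / dof
    se_slope = np.sqrt(sigma2 / sxx)
    se_intercept = np.sqrt(sigma2 * (1.0 / n + x.mean() ** 2 / sxx))
    if se_slope > 0:
        t = slope / se_slope
        p = 2 * stats.t.sf(abs(t), dof)
    else:
        p = 0.0 if slope != 0 else 1.0
    t_crit = stats.t.ppf(0.5 + conf_level / 2, dof)
    return RegressionResult(slope=float(slope), intercept=float(intercept),
                            r2=float(r2), r2_adj=float(r2_adj), p=float(p),
                            n=n, conf_level=conf_level,
                            slope_halfwidth=float(t_crit * se_slope),
                            intercept_halfwidth=float(t_crit * se_intercept))


def seasonal_ft_difference(efs: pd.DataFrame, meta: pd.DataFrame,
                           metric: str = "ft_mic",
                           order: tuple[str, str] = ("August", "December")) -> pd.Series:
    """Per-reservoir seasonal difference in the mean F:T ratio.

    Delta = mean(metric | first season) - mean(metric | second season); the
    default convention is August - December.  Reservoirs missing a season
    are skipped.
    """
    meta = meta.loc[efs.index]
    deltas = {}
    for reservoir, sub in meta.groupby("reservoir"):
        means = {}
        for season in order:
            ids = sub.index[sub["season"] == season]
            if len(ids) == 0:
                break
            means[season] = efs.loc[ids, metric].mean()
        if len(means) == 2:
            deltas[reservoir] = means[order[0]] - means[order[1]]
    return pd.Series(deltas, name=f"delta_{metric}")


def hydraulic_regression(deltas: pd.Series, hydraulic_load: pd.Series,
                         conf_level: float = 0.95) -> RegressionResult:
    """Regress seasonal F:T differences on log10 hydraulic load."""
    joined = pd.concat([deltas, hydraulic_load], axis=1, join="inner").dropna()
    if joined.shape[0] < 3:
        raise ValueError("need at least 3 reservoirs")
    h = joined.iloc[:, 1].to_numpy(dtype=float)
    if (h <= 0).any():
        raise ValueError("hydraulic load must be positive")
    return linfit(np.log10(h), joined.iloc[:, 0].to_numpy(dtype=float),
                  conf_level=conf_level)
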