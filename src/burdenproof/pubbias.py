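"""Publication/reporting-bias diagnostics.

Egger's regression test regresses the model residuals on their sampling
standard errors: under no small-study bias the residual mean does not
depend on the SE, so a significant slope flags asymmetry of the funnel.
The regression is weighted by the inverse marginal variance
1/(sigma^2 + gamma-hat) — the same scale the likelihood uses — which
reduces to the canonical 1/SE^2 weighting when gamma-hat = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import MetaRegressionResults

__all__ = ["EggerResult", "eggers_test", "funnel_data", "eggers_test_from_fit"]


@dataclass(frozen=True)
class EggerResult:
    """Egger regression slope, its SE and two-sided p-value.

    ``flagged`` is True iff p < alpha; ``diagnostic`` carries a note for
    degenerate designs (e.g. all SEs identical), in which case the test
    is reported as not flagged.
    """

    slope: float
    se_slope: float
    p_value: float
    flagged: bool
    alpha: float = 0.05
    diagnostic: str = ""


def eggers_test(
    residuals: np.ndarray,
    ses: np.ndarray,
    alpha: float = 0.05,
    gamma: float = 0.0,
) -> EggerResult:
    """Weighted regression of residuals on SEs (intercept included).

    Weights are 1/(se^2 + gamma); the slope's two-sided p-value uses the
    t distribution with n-2 degrees of freedom.
    """
    r = np.asarray(residuals, dtype=float)
    s = np.asarray(ses, dtype=float)
    if r.shape != s.shape or r.ndim != 1:
        raise ValueError("residuals and ses must be 1-d arrays of equal length")
    n = r.size
    if n < 3:
        raise ValueError("Egger's test needs at least 3 observations")
    if np.any(s <= 0):
        raise ValueError("all SEs must be positive")
    if np.ptp(s) == 0:
        return EggerResult(
            slope=float("nan"), se_slope=float("nan"), p_value=1.0,
            flagged=False, alpha=alpha,
            diagnostic="zero design variance: all SEs identical, slope undefined",
        )

    w = 1.0 / (s**2 + gamma)
    X = np.column_stack([np.ones(n), s])
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    rw = r * sw
    XtX = Xw.T @ Xw
    coef = np.linalg.solve(XtX, Xw.T @ rw)
    resid = rw - Xw @ coef
    df = n - 2
    s2 = float(resid @ resid) / df
    cov = s2 * np.linalg.inv(XtX)
    slope = float(coef[1])
    se_slope = float(np.sqrt(cov[1, 1]))
    if se_slope == 0.0:
        p = 0.0 if slope != 0 else 1.0
    else:
        p = 2.0 * float(stats.t.sf(abs(slope) / se_slope, df))
    return EggerResult(slope=slope, se_slope=se_slope, p_value=p,
                       flagged=p < alpha, alpha=alpha)


def eggers_test_from_fit(results: MetaRegressionResults, alpha: float = 0.05,
                         retained_only: bool = True) -> EggerResult:
    """Egger's test on the fitted model's residuals (retained
    observations by default, i.e. after outlier trimming)."""
    ds = results.model.dataset
    res = results.residuals()
    ses = np.array([o.se_log_rr for o in ds])
    if retained_only:
        keep = results.trim_mask.astype(bool)
        res, ses = res[keep], ses[keep]
    return eggers_test(res, ses, alpha=alpha, gamma=results.gamma)


def funnel_data(results: MetaRegressionResults) -> pd.DataFrame:
    """Per-observation funnel-plot table: residual vs SE, with trimmed
    points flagged (they are included so funnels show what was removed)."""
    ds = results.model.dataset
    res = results.residuals()
    return pd.DataFrame({
        "study_id": [o.study_id for o in ds],
        "residual": res,
        "se": [o.se_log_rr for o in ds],
        "trimmed": ~results.trim_mask.astype(bool),
    })
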