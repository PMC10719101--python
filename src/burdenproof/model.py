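"""Mixed-effects meta-regression on log relative risks.

Model
-----
For observation j of study i,

    y_ij = beta0 + x_ij' beta + u_i + eps_ij,
    u_i ~ N(0, gamma),   eps_ij ~ N(0, sigma_ij^2),

with y the reported log effect, sigma_ij its reported sampling SE, x_ij
binary bias covariates, u_i a study-level random effect inducing
within-study correlation, and gamma >= 0 the between-study heterogeneity
variance. Estimation is maximum marginal likelihood: beta is profiled out
in closed form by GLS at each gamma, and the profile likelihood is
maximised over gamma >= 0 by a bounded one-dimensional search with an
explicit boundary check at gamma = 0.

The uncertainty of gamma-hat comes from the Fisher information of the
marginal likelihood,

    I(gamma) = 1/2 * sum_g tr[(V_g^{-1} dV_g/dgamma)^2]
             = 1/2 * sum_g (1' V_g^{-1} 1)^2,

where V_g = diag(sigma^2) + gamma * 11' is the marginal covariance of
study g; sd(gamma-hat) = I(gamma-hat)^{-1/2}. When gamma-hat = 0 the same
(one-sided) information is used.

Likelihood-based trimming ranks observations by their marginal
log-density under the current fit, retains the top ceil((1-trim)*n),
refits, and iterates to a fixed point — the standard trimmed-MLE scheme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .data import CovariateSpec, RiskOutcomeDataset, ValidationError

__all__ = ["MetaRegression", "MetaRegressionResults", "FitError",
           "select_bias_covariates"]

_LOG_2PI = math.log(2.0 * math.pi)


class FitError(RuntimeError):
    """Raised when the likelihood optimisation fails to produce a usable fit."""


def _group_slices(groups: np.ndarray) -> list[np.ndarray]:
    out = []
    for g in np.unique(groups):
        out.append(np.flatnonzero(groups == g))
    return out


def _profile_beta(y, X, se2, groups_idx, gamma):
    """GLS beta-hat and building blocks at fixed gamma, via Woodbury.

    V_g^{-1} = D^{-1} - gamma/(1+gamma t_g) d d',  d = D^{-1} 1, t_g = sum 1/sigma^2.
    """
    n, p = X.shape
    XtViX = np.zeros((p, p))
    XtViy = np.zeros(p)
    logdet = 0.0
    parts = []
    for idx in groups_idx:
        d = 1.0 / se2[idx]
        t = d.sum()
        c = gamma / (1.0 + gamma * t)
        Xg = X[idx]
        yg = y[idx]
        dX = Xg * d[:, None]
        dy = yg * d
        XtViX += Xg.T @ dX - c * np.outer(dX.sum(axis=0), dX.sum(axis=0))
        XtViy += Xg.T @ dy - c * dX.sum(axis=0) * dy.sum()
        logdet += np.log(se2[idx]).sum() + math.log1p(gamma * t)
        parts.append((idx, d, t, c))
    try:
        beta = np.linalg.solve(XtViX, XtViy)
    except np.linalg.LinAlgError as exc:
        raise FitError("singular design matrix (collinear covariates)") from exc
    return beta, XtViX, logdet, parts


def _loglik_at(y, X, se2, groups_idx, gamma):
    beta, XtViX, logdet, parts = _profile_beta(y, X, se2, groups_idx, gamma)
    r = y - X @ beta
    quad = 0.0
    for idx, d, t, c in parts:
        rg = r[idx]
        dr = rg * d
        quad += rg @ dr - c * dr.sum() ** 2
    ll = -0.5 * (len(y) * _LOG_2PI + logdet + quad)
    return ll, beta, XtViX


@dataclass
class MetaRegressionResults:
    """Fitted state of the mixed-effects meta-regression.

    ``params`` holds the intercept (pooled log RR at the covariate
    reference level) followed by the selected covariate coefficients;
    ``cov_params`` is their GLS covariance at gamma-hat.
    """

    model: "MetaRegression"
    params: np.ndarray
    cov_params: np.ndarray
    gamma: float
    sd_gamma: float
    loglik: float
    trim_mask: np.ndarray  # True = retained
    exog_names: tuple[str, ...]
    converged: bool = True
    n_iter_trim: int = 0

    # -- convenience accessors ------------------------------------------
    @property
    def beta0(self) -> float:
        return float(self.params[0])

    @property
    def var_beta0(self) -> float:
        return float(self.cov_params[0, 0])

    @property
    def beta_cov(self) -> dict[str, float]:
        return {n: float(b) for n, b in zip(self.exog_names[1:], self.params[1:])}

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def n_obs_retained(self) -> int:
        return int(self.trim_mask.sum())

    @property
    def selected_covariates(self) -> tuple[str, ...]:
        return self.exog_names[1:]

    def predict_reference(self) -> tuple[float, float]:
        """Pooled log RR and its variance with every covariate at its
        gold-standard reference level (0): the bias-adjusted effect."""
        return self.beta0, self.var_beta0

    def fixed_effect_ci(self, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2.0)
        half = z * math.sqrt(self.var_beta0)
        return self.beta0 - half, self.beta0 + half

    def residuals(self, dataset: RiskOutcomeDataset | None = None) -> np.ndarray:
        """Observed log RR minus the covariate-adjusted fixed prediction,
        for every observation (retained and trimmed)."""
        ds = dataset if dataset is not None else self.model.dataset
        y, _, _, X = ds.arrays(self.exog_names[1:])
        return y - X @ self.params

    def summary(self) -> str:
        lines = [
            "Mixed-effects meta-regression (log relative risk)",
            "=" * 52,
            f"risk / outcome        : {self.model.dataset.risk_name} / {self.model.dataset.outcome_name}",
            f"observations retained : {self.n_obs_retained} / {len(self.trim_mask)}",
            f"studies               : {self.model.dataset.n_studies}",
            f"log-likelihood        : {self.loglik:.6f}",
            f"gamma (between-study) : {self.gamma:.6f} (sd {self.sd_gamma:.6f})",
            "",
            f"{'term':<28}{'coef':>12}{'se':>12}{'z':>10}",
        ]
        for name, b, s in zip(self.exog_names, self.params, self.bse):
            z = b / s if s > 0 else float("nan")
            lines.append(f"{name:<28}{b:>12.6f}{s:>12.6f}{z:>10.3f}")
        return "\n".join(lines)

    def to_report_frame(self):
        """Per-observation table: trim flag, residual, weight."""
        import pandas as pd

        ds = self.model.dataset
        y, se, _, _ = ds.arrays()
        res = self.residuals()
        return pd.DataFrame({
            "study_id": [o.study_id for o in ds],
            "log_rr": y,
            "se_log_rr": se,
            "retained": self.trim_mask.astype(bool),
            "residual": res,
            "weight": 1.0 / (se**2 + self.gamma),
        })


class MetaRegression:
    """Mixed-effects meta-regression model for one risk–outcome pair.

    Parameters
    ----------
    dataset : RiskOutcomeDataset
        Validated evidence base; must contain at least three distinct
        studies.
    covariates : sequence of str, optional
        Bias covariates entering the fixed-effect design (intercept is
        always included).
    """

    MAX_TRIM_ITER = 100
    GAMMA_MAX_FACTOR = 10.0

    def __init__(self, dataset: RiskOutcomeDataset, covariates: Sequence[str] = (),
                 min_studies: int = 3):
        dataset.require_min_studies(min_studies)
        unknown = set(covariates) - set(dataset.covariate_names)
        if unknown:
            raise ValidationError(f"unknown covariate(s): {sorted(unknown)}")
        self.dataset = dataset
        self.covariates = tuple(covariates)
        self.exog_names = ("intercept",) + self.covariates

    # -- single (untrimmed) fit on a subset ------------------------------
    def _fit_subset(self, keep: np.ndarray, fix_gamma: float | None = None):
        y, se, g, X = self.dataset.arrays(self.covariates)
        y, se, g, X = y[keep], se[keep], g[keep], X[keep]
        se2 = se**2
        groups_idx = _group_slices(g)

        if fix_gamma is not None:
            gamma_hat = float(fix_gamma)
            ll, beta, XtViX = _loglik_at(y, X, se2, groups_idx, gamma_hat)
        else:
            gamma_max = self.GAMMA_MAX_FACTOR * float(np.var(y)) + 1.0

            def neg(gamma):
                return -_loglik_at(y, X, se2, groups_idx, gamma)[0]

            res = optimize.minimize_scalar(
                neg, bounds=(0.0, gamma_max), method="bounded",
                options={"xatol": 1e-12, "maxiter": 500},
            )
            gamma_hat = float(res.x)
            # the bounded search cannot land exactly on the boundary;
            # project to 0 when the boundary is at least as good
            if neg(0.0) <= res.fun:
                gamma_hat = 0.0
            ll, beta, XtViX = _loglik_at(y, X, se2, groups_idx, gamma_hat)

        info = self._gamma_information(se2, groups_idx, gamma_hat)
        sd_gamma = math.sqrt(1.0 / info) if info > 0 else float("inf")
        cov = np.linalg.inv(XtViX)
        return beta, cov, gamma_hat, sd_gamma, ll, (y, se2, X, groups_idx)

    @staticmethod
    def _gamma_information(se2, groups_idx, gamma):
        """I(gamma) = 1/2 sum_g (1' V_g^{-1} 1)^2 with V_g = D + gamma 11'."""
        info = 0.0
        for idx in groups_idx:
            t = (1.0 / se2[idx]).sum()
            info += (t / (1.0 + gamma * t)) ** 2
        return 0.5 * info

    def _obs_scores(self, beta, gamma) -> np.ndarray:
        """Per-observation marginal log-density used to rank for trimming."""
        y, se, _, X = self.dataset.arrays(self.covariates)
        var = se**2 + gamma
        r = y - X @ beta
        return -0.5 * (_LOG_2PI + np.log(var) + r**2 / var)

    def fit(
        self,
        trim: float = 0.0,
        trim_min_obs: int = 10,
        fix_gamma: float | None = None,
    ) -> MetaRegressionResults:
        """Maximise the (optionally trimmed) marginal likelihood.

        Trimming removes the ``n - ceil((1 - trim) * n)`` observations
        least consistent with the fit, and is activated only when the
        dataset has at least ``trim_min_obs`` observations.
        """
        if not (0.0 <= trim <= 0.5):
            raise ValueError("trim must lie in [0, 0.5]")
        n = self.dataset.n_obs
        keep = np.ones(n, dtype=bool)
        n_keep = int(math.ceil((1.0 - trim) * n))
        trimming = trim > 0 and n >= trim_min_obs and n_keep < n

        beta, cov, gamma_hat, sd_gamma, ll, _ = self._fit_subset(keep, fix_gamma)
        n_iter = 0
        if trimming:
            se_all = np.array([o.se_log_rr for o in self.dataset])
            order_tiebreak = np.lexsort((np.arange(n), se_all))  # smaller SE first, then input order
            rank_of = np.empty(n, dtype=int)
            rank_of[order_tiebreak] = np.arange(n)
            for n_iter in range(1, self.MAX_TRIM_ITER + 1):
                scores = self._obs_scores(beta, gamma_hat)
                # retain the n_keep highest-scoring observations;
                # ties: smaller SE retained first, then input order
                order = np.lexsort((rank_of, -scores))
                new_keep = np.zeros(n, dtype=bool)
                new_keep[order[:n_keep]] = True
                if np.array_equal(new_keep, keep):
                    break
                keep = new_keep
                beta, cov, gamma_hat, sd_gamma, ll, _ = self._fit_subset(keep, fix_gamma)

        return MetaRegressionResults(
            model=self,
            params=np.asarray(beta, dtype=float),
            cov_params=np.asarray(cov, dtype=float),
            gamma=gamma_hat,
            sd_gamma=sd_gamma,
            loglik=float(ll),
            trim_mask=keep,
            exog_names=self.exog_names,
            n_iter_trim=n_iter,
        )


def _lasso_entry_order(dataset: RiskOutcomeDataset, candidates: Sequence[str]) -> list[str]:
    """Order candidates by entry along the L1 path of the SE-weighted design.

    Observations are standardised by their sampling SEs; the (weighted)
    intercept is projected out of the response and the candidate columns
    before the path is computed, so it is effectively unpenalised.
    """
    from sklearn.linear_model import lasso_path

    y, se, _, X = dataset.arrays(candidates)
    w = 1.0 / se
    yw = y * w
    Z = X * w[:, None]  # column 0 is the weighted intercept
    z0 = Z[:, 0]
    denom = z0 @ z0
    proj = lambda v: v - z0 * ((z0 @ v) / denom)
    yr = proj(yw)
    Xr = np.column_stack([proj(Z[:, j]) for j in range(1, Z.shape[1])])

    alphas, coefs, _ = lasso_path(Xr, yr, alphas=100, eps=1e-3)
    nz = np.abs(coefs) > 1e-12
    entry = np.full(len(candidates), nz.shape[1] + 1)
    for j in range(len(candidates)):
        hit = np.flatnonzero(nz[j])
        if hit.size:
            entry[j] = hit[0]
    final = np.abs(coefs[:, -1])
    order = sorted(
        range(len(candidates)),
        key=lambda j: (entry[j], -final[j], candidates[j]),
    )
    return [candidates[j] for j in order if entry[j] <= nz.shape[1]]


def select_bias_covariates(
    dataset: RiskOutcomeDataset,
    candidates: Sequence[CovariateSpec] | Sequence[str],
    alpha: float = 0.05,
) -> list[str]:
    """Stepwise bias-covariate selection: Lasso pre-screening for entry
    order, then an unregularised Wald test for each entrant.

    Candidates enter in the order they appear along the L1 regularisation
    path; each is kept iff its coefficient is significant at ``alpha``
    (two-sided) in a mixed-model refit containing the covariates already
    kept. Deterministic given the dataset.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    names = [c.name if isinstance(c, CovariateSpec) else c for c in candidates]
    for c in candidates:
        if isinstance(c, CovariateSpec) and not c.testable:
            raise ValidationError(f"covariate {c.name!r} is not testable in this dataset")
    if not names:
        return []

    ordered = _lasso_entry_order(dataset, names)
    kept: list[str] = []
    for name in ordered:
        trial = kept + [name]
        res = MetaRegression(dataset, covariates=trial).fit(trim=0.0)
        j = trial.index(name) + 1  # position after intercept
        se_j = math.sqrt(res.cov_params[j, j])
        if se_j == 0:
            continue
        z = res.params[j] / se_j
        p = 2.0 * stats.norm.sf(abs(z))
        if p < alpha:
            kept.append(name)
    return kept
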