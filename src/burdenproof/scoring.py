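"""Evidence metrics: uncertainty intervals, BPRF, ROS and star ratings.

Given the fitted pooled log relative risk mu with fixed-effect variance
v and between-study heterogeneity gamma-hat with uncertainty sd(gamma),
the scoring layer reports

* a 95% UI without heterogeneity,  exp(mu +/- 1.96 sqrt(v));
* a 95% UI with heterogeneity taken at its 95th quantile,
  gamma* = gamma-hat + 1.645 sd(gamma):  exp(mu +/- 1.96 sqrt(v + gamma*));
* the burden-of-proof risk function (BPRF): the 5th-quantile estimate of
  the RR closest to the null, inclusive of heterogeneity — for a harmful
  risk exp(mu - 1.645 sqrt(v + gamma*)), the most conservative relative
  risk consistent with the data;
* the risk–outcome score ROS = signed log(BPRF)/2 (positive = evidence
  of association), and its 0–5 star discretisation.

A zero-star rating is assigned when the 95% UI *without* heterogeneity
crosses the null RR of one; BPRF and ROS are then not reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "Z95", "Z90_ONESIDED", "STAR_THRESHOLDS", "EvidenceScore",
    "compute_uis", "gamma_95th_quantile", "compute_bprf", "compute_ros",
    "star_rating", "excess_risk_percent", "score_pair",
]

Z95 = 1.959963984540054        # two-sided 95%
Z90_ONESIDED = 1.6448536269514722  # one-sided 95% (5th/95th quantile)

#: upper edges of the ROS bins for 1..4 stars; above the last edge = 5 stars
STAR_THRESHOLDS = (0.0, 0.14, 0.41, 0.62)


@dataclass(frozen=True)
class EvidenceScore:
    """One scored risk–outcome pair (the published-table row)."""

    risk_name: str
    outcome_name: str
    rr: float
    ui_no_gamma: tuple[float, float]
    ui_with_gamma: tuple[float, float]
    bprf: float | None
    ros: float | None
    stars: int
    pub_bias: bool
    n_studies: int
    direction: str = "harmful"
    gamma: float = float("nan")
    selected_covariates: tuple[str, ...] = ()
    n_trimmed: int = 0

    def __post_init__(self) -> None:
        if self.direction not in ("harmful", "protective"):
            raise ValueError("direction must be 'harmful' or 'protective'")
        if (self.stars == 0) != (self.ros is None):
            raise ValueError("ROS must be absent exactly when the rating is zero stars")


def gamma_95th_quantile(gamma_hat: float, sd_gamma: float) -> float:
    """95th quantile of the heterogeneity estimate under a normal
    approximation, truncated below at zero."""
    if gamma_hat < 0 or sd_gamma < 0:
        raise ValueError("gamma_hat and sd_gamma must be >= 0")
    return max(0.0, gamma_hat + Z90_ONESIDED * sd_gamma)


def compute_uis(
    log_rr_ref: float, var_fixed: float, gamma_hat: float, sd_gamma: float
) -> tuple[tuple[float, float], tuple[float, float]]:
    """95% UIs without and with the 95th-quantile heterogeneity term."""
    if var_fixed <= 0:
        raise ValueError("var_fixed must be > 0")
    g_star = gamma_95th_quantile(gamma_hat, sd_gamma)
    half_no = Z95 * math.sqrt(var_fixed)
    half_with = Z95 * math.sqrt(var_fixed + g_star)
    ui_no = (math.exp(log_rr_ref - half_no), math.exp(log_rr_ref + half_no))
    ui_with = (math.exp(log_rr_ref - half_with), math.exp(log_rr_ref + half_with))
    return ui_no, ui_with


def compute_bprf(
    log_rr_ref: float, var_fixed: float, gamma_star: float, direction: str = "harmful"
) -> float:
    """5th-quantile RR closest to the null, inclusive of heterogeneity."""
    sd_total = math.sqrt(var_fixed + gamma_star)
    if direction == "harmful":
        return math.exp(log_rr_ref - Z90_ONESIDED * sd_total)
    if direction == "protective":
        return math.exp(log_rr_ref + Z90_ONESIDED * sd_total)
    raise ValueError("direction must be 'harmful' or 'protective'")


def compute_ros(bprf: float, direction: str = "harmful") -> float:
    """Risk–outcome score: signed log(BPRF)/2, positive = evidence of
    association in the stated direction."""
    if bprf <= 0:
        raise ValueError("bprf must be > 0")
    if direction == "harmful":
        return math.log(bprf) / 2.0
    if direction == "protective":
        return -math.log(bprf) / 2.0
    raise ValueError("direction must be 'harmful' or 'protective'")


def star_rating(
    ros: float | None,
    significant_no_gamma: bool,
    thresholds: tuple[float, float, float, float] = STAR_THRESHOLDS,
) -> int:
    """Discretise the ROS into 0–5 stars.

    Zero stars whenever the no-heterogeneity UI crosses the null
    (``significant_no_gamma`` False); otherwise 1 star for ROS <= 0,
    and the bins (0, 0.14], (0.14, 0.41], (0.41, 0.62], (0.62, inf)
    give 2..5 stars.
    """
    if not significant_no_gamma:
        if ros is not None:
            raise ValueError("ROS must not be supplied for a non-significant pair")
        return 0
    if ros is None:
        raise ValueError("ROS required for a significant pair")
    t1, t2, t3, t4 = thresholds
    if ros <= t1:
        return 1
    if ros <= t2:
        return 2
    if ros <= t3:
        return 3
    if ros <= t4:
        return 4
    return 5


def excess_risk_percent(bprf: float) -> float:
    """Most conservative excess risk implied by the BPRF: (BPRF-1)*100,
    read as 'at least an X% increase in risk'."""
    if bprf <= 0:
        raise ValueError("bprf must be > 0")
    return (bprf - 1.0) * 100.0


def score_pair(
    risk_name: str,
    outcome_name: str,
    log_rr_ref: float,
    var_fixed: float,
    gamma_hat: float,
    sd_gamma: float,
    n_studies: int,
    pub_bias: bool = False,
    direction: str = "harmful",
    star_thresholds: tuple[float, float, float, float] = STAR_THRESHOLDS,
    selected_covariates: tuple[str, ...] = (),
    n_trimmed: int = 0,
) -> EvidenceScore:
    """Assemble the full evidence-score row from fitted quantities."""
    ui_no, ui_with = compute_uis(log_rr_ref, var_fixed, gamma_hat, sd_gamma)
    if direction == "harmful":
        significant = ui_no[0] > 1.0
    else:
        significant = ui_no[1] < 1.0
    if significant:
        g_star = gamma_95th_quantile(gamma_hat, sd_gamma)
        bprf = compute_bprf(log_rr_ref, var_fixed, g_star, direction)
        ros = compute_ros(bprf, direction)
        stars = star_rating(ros, True, star_thresholds)
    else:
        bprf = ros = None
        stars = 0
    return EvidenceScore(
        risk_name=risk_name,
        outcome_name=outcome_name,
        rr=math.exp(log_rr_ref),
        ui_no_gamma=ui_no,
        ui_with_gamma=ui_with,
        bprf=bprf,
        ros=ros,
        stars=stars,
        pub_bias=pub_bias,
        n_studies=n_studies,
        direction=direction,
        gamma=gamma_hat,
        selected_covariates=tuple(selected_covariates),
        n_trimmed=n_trimmed,
    )
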