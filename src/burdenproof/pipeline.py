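"""Per-pair orchestration: covariate testability -> selection -> trimmed
mixed fit -> reference prediction -> UIs -> BPRF/ROS/stars -> Egger.

Also runs the standard sensitivity analyses (no-trim toggle,
covariate-based row exclusion) and renders the master report tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .data import RiskOutcomeDataset, ValidationError, derive_testable_covariates
from .model import MetaRegression, MetaRegressionResults, select_bias_covariates
from .pubbias import EggerResult, eggers_test_from_fit, funnel_data
from .scoring import STAR_THRESHOLDS, EvidenceScore, score_pair

__all__ = ["PipelineConfig", "PairResult", "run_pair", "run_sensitivity",
           "render_reports"]

logger = logging.getLogger("burdenproof")

#: theoretical minimum risk exposure level for both risk factors (no
#: exposure); recorded as metadata, nothing is computed from it.
TMREL = 0.0


@dataclass(frozen=True)
class PipelineConfig:
    """All analysis constants in one place (none are hard-coded downstream)."""

    trim_proportion: float = 0.10
    trim_min_obs: int = 10
    alpha_selection: float = 0.05
    alpha_egger: float = 0.05
    gamma_quantile: float = 0.95
    star_thresholds: tuple[float, float, float, float] = STAR_THRESHOLDS
    direction: str = "harmful"
    min_studies: int = 3
    repeat_adjustment: str = "sqrt"
    select_before_trim: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.trim_proportion <= 0.5):
            raise ValueError("trim_proportion must lie in [0, 0.5]")
        if list(self.star_thresholds) != sorted(self.star_thresholds) or len(
            set(self.star_thresholds)
        ) != 4:
            raise ValueError("star_thresholds must be four strictly increasing values")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "star_thresholds" in raw:
            raw["star_thresholds"] = tuple(raw["star_thresholds"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "trim_proportion": self.trim_proportion,
            "trim_min_obs": self.trim_min_obs,
            "alpha_selection": self.alpha_selection,
            "alpha_egger": self.alpha_egger,
            "gamma_quantile": self.gamma_quantile,
            "star_thresholds": list(self.star_thresholds),
            "direction": self.direction,
            "min_studies": self.min_studies,
            "repeat_adjustment": self.repeat_adjustment,
            "select_before_trim": self.select_before_trim,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


@dataclass(frozen=True)
class PairResult:
    """Everything produced for one risk–outcome pair."""

    score: EvidenceScore
    fit: MetaRegressionResults
    egger: EggerResult
    selected_covariates: tuple[str, ...]
    sensitivity: dict[str, EvidenceScore] = field(default_factory=dict)


@dataclass(frozen=True)
class SensitivitySpec:
    """A named sensitivity analysis: either the no-trim toggle or a
    row filter excluding observations with a covariate set to 1."""

    name: str
    no_trim: bool = False
    exclude_covariate: str | None = None


def run_pair(dataset: RiskOutcomeDataset, config: PipelineConfig = PipelineConfig()) -> PairResult:
    """Execute the full analysis for one risk–outcome pair.

    Raises :class:`ValidationError` if the dataset has fewer than the
    minimum number of distinct studies.
    """
    if dataset.n_studies < config.min_studies:
        raise ValidationError(
            f"refusing to fit {dataset.risk_name}/{dataset.outcome_name}: "
            f"{dataset.n_studies} studies found, at least {config.min_studies} "
            "studies are required"
        )

    specs = derive_testable_covariates(dataset)
    testable = [s for s in specs if s.testable]
    logger.info("%s/%s: %d observations, %d studies, %d testable covariates",
                dataset.risk_name, dataset.outcome_name, dataset.n_obs,
                dataset.n_studies, len(testable))

    selected = select_bias_covariates(dataset, testable, alpha=config.alpha_selection)
    logger.info("selected covariates: %s", selected or "none")

    model = MetaRegression(dataset, covariates=selected)
    fit = model.fit(trim=config.trim_proportion, trim_min_obs=config.trim_min_obs)
    logger.info("fit: beta0=%.4f gamma=%.5f (sd %.5f), trimmed %d/%d",
                fit.beta0, fit.gamma, fit.sd_gamma,
                len(fit.trim_mask) - fit.n_obs_retained, len(fit.trim_mask))

    egger = eggers_test_from_fit(fit, alpha=config.alpha_egger)
    log_rr_ref, var_ref = fit.predict_reference()
    score = score_pair(
        risk_name=dataset.risk_name,
        outcome_name=dataset.outcome_name,
        log_rr_ref=log_rr_ref,
        var_fixed=var_ref,
        gamma_hat=fit.gamma,
        sd_gamma=fit.sd_gamma,
        n_studies=dataset.n_studies,
        pub_bias=egger.flagged,
        direction=config.direction,
        star_thresholds=config.star_thresholds,
        selected_covariates=tuple(selected),
        n_trimmed=len(fit.trim_mask) - fit.n_obs_retained,
    )
    return PairResult(score=score, fit=fit, egger=egger,
                      selected_covariates=tuple(selected))


def run_sensitivity(
    dataset: RiskOutcomeDataset,
    config: PipelineConfig,
    spec: SensitivitySpec,
) -> EvidenceScore:
    """Re-run the pair under a sensitivity specification."""
    cfg = config
    ds = dataset
    if spec.no_trim:
        cfg = replace(cfg, trim_proportion=0.0)
    if spec.exclude_covariate is not None:
        name = spec.exclude_covariate
        if name not in dataset.covariate_names:
            raise ValidationError(f"unknown covariate for sensitivity filter: {name!r}")
        keep = np.array([o.covariates.get(name, 0) == 0 for o in dataset], dtype=bool)
        if keep.all():
            logger.warning("sensitivity %r: filter on %r matched no rows; dataset unchanged",
                           spec.name, name)
        else:
            ds = dataset.subset(keep)
    return run_pair(ds, cfg).score


def _fmt(x: float | None, nd: int = 2) -> str:
    return "N/A" if x is None else f"{x:.{nd}f}"


def render_reports(results: Sequence[PairResult]) -> dict[str, pd.DataFrame]:
    """Master summary table plus per-pair forest and funnel data.

    The summary is ordered by descending ROS (zero-star rows, which have
    no ROS, come last); BPRF/ROS cells of zero-star rows render "N/A".
    """
    if not results:
        raise ValueError("no completed pairs to report")

    order = sorted(
        range(len(results)),
        key=lambda i: (
            results[i].score.ros is None,
            -(results[i].score.ros if results[i].score.ros is not None else 0.0),
        ),
    )
    rows = []
    for i in order:
        s = results[i].score
        rows.append({
            "risk": s.risk_name,
            "outcome": s.outcome_name,
            "rr": f"{s.rr:.2f}",
            "ui_no_gamma": f"({s.ui_no_gamma[0]:.2f}, {s.ui_no_gamma[1]:.2f})",
            "ui_with_gamma": f"({s.ui_with_gamma[0]:.2f}, {s.ui_with_gamma[1]:.2f})",
            "bprf": _fmt(s.bprf),
            "ros": _fmt(s.ros),
            "stars": s.stars,
            "pub_bias": "Yes" if s.pub_bias else "No",
            "n_studies": s.n_studies,
            "selected_covariates": "; ".join(s.selected_covariates) or "None",
            "n_trimmed": s.n_trimmed,
        })
    summary = pd.DataFrame(rows)

    forest = {}
    funnel = {}
    for r in results:
        ds = r.fit.model.dataset
        key = f"{ds.risk_name}__{ds.outcome_name}"
        y = np.array([o.log_rr for o in ds])
        se = np.array([o.se_log_rr for o in ds])
        forest[key] = pd.DataFrame({
            "study_id": [o.study_id for o in ds],
            "rr": np.exp(y),
            "ci_lower": np.exp(y - 1.959963984540054 * se),
            "ci_upper": np.exp(y + 1.959963984540054 * se),
            "trimmed": ~r.fit.trim_mask.astype(bool),
            **{f"cv_{n}": [o.covariates.get(n, 0) for o in ds]
               for n in sorted(ds.covariate_names)},
        })
        funnel[key] = funnel_data(r.fit)

    return {"summary": summary, "forest": forest, "funnel": funnel}
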