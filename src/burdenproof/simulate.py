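"""Synthetic risk–outcome evidence bases with known ground truth.

The generator draws study-level log relative risks with the same
statistical structure the meta-regression assumes: a pooled log effect
``beta0``, additive log-scale shifts for binary bias covariates, a
study-level random effect with variance ``gamma``, and independent
sampling noise with observation-specific standard errors. Optional
contamination adds mean-shifted outliers (what trimming is designed to
remove) and a linear dependence of the mean on the sampling SE
(``egger_slope``) to emulate small-study/publication bias.

Defaults mirror the scale of the extracted evidence bases this pipeline
targets: a dozen studies with one or two observations each, SEs spread
over (0.05, 0.5), covariate prevalence 0.3.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .data import CovariateSpec, EffectObservation, RiskOutcomeDataset

__all__ = ["SyntheticTruth", "simulate_dataset", "simulate_null_ensemble",
           "write_truth", "read_truth"]


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth parameters of a generated evidence base."""

    beta0: float = float(np.log(2.0))
    beta_cov: Mapping[str, float] = field(default_factory=dict)
    gamma: float = 0.04
    se_range: tuple[float, float] = (0.05, 0.5)
    n_studies: int = 12
    obs_per_study: int | tuple[int, int] = (1, 2)
    covariate_prevalence: float = 0.3
    outlier_fraction: float = 0.0
    outlier_shift: float = 0.0
    egger_slope: float = 0.0
    seed: int = 0
    outlier_indices: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        lo, hi = self.se_range
        if not (0 < lo <= hi):
            raise ValueError("se_range must satisfy 0 < low <= high")
        if not (0.0 <= self.outlier_fraction <= 0.3):
            raise ValueError("outlier_fraction must lie in [0, 0.3]")
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")


def _obs_counts(truth: SyntheticTruth, rng: np.random.Generator) -> np.ndarray:
    if isinstance(truth.obs_per_study, int):
        return np.full(truth.n_studies, truth.obs_per_study, dtype=int)
    lo, hi = truth.obs_per_study
    return rng.integers(lo, hi + 1, size=truth.n_studies)


def simulate_dataset(
    truth: SyntheticTruth,
    risk_name: str = "synthetic_risk",
    outcome_name: str = "synthetic_outcome",
) -> tuple[RiskOutcomeDataset, SyntheticTruth]:
    """Draw one evidence base; reproducible from ``truth.seed``.

    Returns the dataset together with the truth record, whose
    ``outlier_indices`` field is filled with the positions of the
    contaminated observations (in dataset order) for recovery tests.
    """
    rng = np.random.default_rng(truth.seed)
    counts = _obs_counts(truth, rng)
    cov_names = sorted(truth.beta_cov)

    observations: list[EffectObservation] = []
    for i, k in enumerate(counts):
        u_i = rng.normal(0.0, np.sqrt(truth.gamma)) if truth.gamma > 0 else 0.0
        for _ in range(int(k)):
            sigma = rng.uniform(*truth.se_range)
            covs = {name: int(rng.random() < truth.covariate_prevalence) for name in cov_names}
            mean = truth.beta0 + sum(truth.beta_cov[n] * covs[n] for n in cov_names)
            y = mean + u_i + truth.egger_slope * sigma + rng.normal(0.0, sigma)
            observations.append(
                EffectObservation(
                    study_id=f"study_{i:03d}", log_rr=float(y), se_log_rr=float(sigma),
                    covariates=covs,
                )
            )

    n = len(observations)
    n_out = int(round(truth.outlier_fraction * n))
    out_idx: tuple[int, ...] = ()
    if n_out > 0:
        out_idx = tuple(sorted(rng.choice(n, size=n_out, replace=False).tolist()))
        for j in out_idx:
            o = observations[j]
            observations[j] = dataclasses.replace(o, log_rr=o.log_rr + truth.outlier_shift)

    specs = tuple(CovariateSpec(n) for n in cov_names)
    dataset = RiskOutcomeDataset(risk_name, outcome_name, tuple(observations), specs)
    return dataset, dataclasses.replace(truth, outlier_indices=out_idx)


def simulate_null_ensemble(template: SyntheticTruth, n_replicates: int) -> list[RiskOutcomeDataset]:
    """Independent null (beta0 = 0) evidence bases with distinct derived seeds."""
    if template.beta0 != 0.0:
        raise ValueError("null ensemble requires a template with beta0 = 0")
    if n_replicates < 0:
        raise ValueError("n_replicates must be >= 0")
    seeds = np.random.SeedSequence(template.seed).generate_state(max(n_replicates, 1)) % (2**31)
    out = []
    for r in range(n_replicates):
        truth = dataclasses.replace(template, seed=int(seeds[r]))
        out.append(simulate_dataset(truth)[0])
    return out


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """Sidecar key–value file recording the generating parameters."""
    lines = []
    for f in dataclasses.fields(truth):
        v = getattr(truth, f.name)
        if isinstance(v, Mapping):
            v = ";".join(f"{k}={v[k]}" for k in sorted(v))
        elif isinstance(v, (tuple, list)):
            v = ",".join(str(x) for x in v)
        lines.append(f"{f.name}: {v}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_truth(path: str | Path) -> SyntheticTruth:
    raw: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if line.strip():
            key, _, val = line.partition(":")
            raw[key.strip()] = val.strip()
    beta_cov = {}
    if raw.get("beta_cov"):
        for item in raw["beta_cov"].split(";"):
            k, _, v = item.partition("=")
            beta_cov[k] = float(v)
    ops: int | tuple[int, int]
    ops_parts = raw["obs_per_study"].split(",")
    ops = int(ops_parts[0]) if len(ops_parts) == 1 else (int(ops_parts[0]), int(ops_parts[1]))
    se_parts = raw["se_range"].split(",")
    out_idx = tuple(int(x) for x in raw.get("outlier_indices", "").split(",") if x)
    return SyntheticTruth(
        beta0=float(raw["beta0"]),
        beta_cov=beta_cov,
        gamma=float(raw["gamma"]),
        se_range=(float(se_parts[0]), float(se_parts[1])),
        n_studies=int(raw["n_studies"]),
        obs_per_study=ops,
        covariate_prevalence=float(raw["covariate_prevalence"]),
        outlier_fraction=float(raw["outlier_fraction"]),
        outlier_shift=float(raw["outlier_shift"]),
        egger_slope=float(raw["egger_slope"]),
        seed=int(raw["seed"]),
        outlier_indices=out_idx,
    )
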