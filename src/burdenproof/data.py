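"""Observation-level data model and extraction-table I/O.

The unit of analysis is one extracted effect size (relative risk, odds
ratio or hazard ratio) comparing exposed with unexposed individuals,
carried on the natural-log scale together with its sampling standard
error, its parent study, and a set of binary bias covariates marking
departures from the gold-standard study design (``cv_`` columns).

Effect measures other than RR are kept on the log scale as-is; the
distinction is handled downstream as a bias covariate rather than by a
rare-disease transformation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Z_95",
    "EffectObservation",
    "CovariateSpec",
    "RiskOutcomeDataset",
    "ValidationError",
    "rr_ci_to_log",
    "adjust_se_for_repeats",
    "derive_testable_covariates",
    "read_extraction_table",
    "read_canonical_table",
    "write_canonical_table",
]

#: two-sided 95% normal quantile used throughout for CI <-> SE conversion
Z_95 = 1.959963984540054

MEASURE_TYPES = ("RR", "OR", "HR")

CANONICAL_COLUMNS = ("study_id", "log_rr", "se_log_rr", "n_repeats")


class ValidationError(ValueError):
    """Raised when an extraction table or observation violates the data contract."""


@dataclass(frozen=True)
class EffectObservation:
    """One extracted effect size on the log-relative-risk scale.

    Parameters
    ----------
    study_id : str
        Opaque study label; observations sharing it share a study-level
        random effect.
    log_rr : float
        Log of the reported effect measure.
    se_log_rr : float
        Sampling standard error of ``log_rr``; must be positive.
    n_repeats : int
        Number of non-mutually-exclusive effect sizes drawn from the same
        sample (1 = unique). Used for the repeated-measurement SE
        adjustment; preserved for audit after adjustment.
    covariates : mapping
        Binary bias-covariate values, name -> {0, 1}.
    """

    study_id: str
    log_rr: float
    se_log_rr: float
    n_repeats: int = 1
    covariates: Mapping[str, int] = field(default_factory=dict)
    subgroup_label: str | None = None
    measure_type: str = "RR"

    def __post_init__(self) -> None:
        if not math.isfinite(self.log_rr):
            raise ValidationError(f"log_rr must be finite, got {self.log_rr!r}")
        if not (math.isfinite(self.se_log_rr) and self.se_log_rr > 0):
            raise ValidationError(f"se_log_rr must be finite and > 0, got {self.se_log_rr!r}")
        if int(self.n_repeats) != self.n_repeats or self.n_repeats < 1:
            raise ValidationError(f"n_repeats must be an integer >= 1, got {self.n_repeats!r}")
        for name, value in self.covariates.items():
            if value not in (0, 1):
                raise ValidationError(
                    f"covariate {name!r} must be 0 or 1, got {value!r}"
                )
        if self.measure_type not in MEASURE_TYPES:
            raise ValidationError(
                f"measure_type must be one of {MEASURE_TYPES}, got {self.measure_type!r}"
            )


@dataclass(frozen=True)
class CovariateSpec:
    """Declaration of a candidate binary bias covariate.

    ``reference_level`` 0 is the gold-standard condition; ``testable`` is
    recomputed against the dataset it is evaluated on (at least two
    observations at each level), never cached across datasets.
    """

    name: str
    reference_level: int = 0
    testable: bool = False


@dataclass
class RiskOutcomeDataset:
    """All extracted observations for one risk–outcome pair."""

    risk_name: str
    outcome_name: str
    observations: tuple[EffectObservation, ...]
    covariate_specs: tuple[CovariateSpec, ...] = ()

    def __post_init__(self) -> None:
        self.observations = tuple(self.observations)
        known = self.covariate_names
        for i, obs in enumerate(self.observations):
            unknown = set(obs.covariates) - set(known)
            if unknown:
                raise ValidationError(
                    f"observation {i} carries unknown covariate(s) {sorted(unknown)}"
                )
        if not self.covariate_specs:
            names = sorted({n for o in self.observations for n in o.covariates})
            self.covariate_specs = tuple(CovariateSpec(n) for n in names)

    @property
    def covariate_names(self) -> tuple[str, ...]:
        if self.covariate_specs:
            return tuple(s.name for s in self.covariate_specs)
        return tuple(sorted({n for o in self.observations for n in o.covariates}))

    @property
    def n_obs(self) -> int:
        return len(self.observations)

    @property
    def n_studies(self) -> int:
        return len({o.study_id for o in self.observations})

    def __iter__(self) -> Iterator[EffectObservation]:
        return iter(self.observations)

    def __len__(self) -> int:
        return len(self.observations)

    def require_min_studies(self, minimum: int = 3) -> None:
        """Enforce the minimum-studies gate applied before any model fit."""
        if self.n_studies < minimum:
            raise ValidationError(
                f"dataset has {self.n_studies} distinct studies; "
                f"at least {minimum} studies are required"
            )

    def to_frame(self) -> pd.DataFrame:
        """Canonical tabular view: fixed column order, covariates sorted by name."""
        names = sorted(self.covariate_names)
        rows = []
        for o in self.observations:
            row = {
                "study_id": o.study_id,
                "log_rr": o.log_rr,
                "se_log_rr": o.se_log_rr,
                "n_repeats": o.n_repeats,
            }
            for n in names:
                row[f"cv_{n}"] = o.covariates.get(n, 0)
            rows.append(row)
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS) + [f"cv_{n}" for n in names])

    def subset(self, keep: Sequence[bool] | np.ndarray) -> "RiskOutcomeDataset":
        keep = np.asarray(keep, dtype=bool)
        if keep.shape != (self.n_obs,):
            raise ValueError("boolean mask length must match number of observations")
        obs = tuple(o for o, k in zip(self.observations, keep) if k)
        return RiskOutcomeDataset(
            self.risk_name, self.outcome_name, obs,
            tuple(CovariateSpec(s.name, s.reference_level) for s in self.covariate_specs),
        )

    # array views used by the model layer -------------------------------
    def arrays(self, covariates: Sequence[str] = ()) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Return (y, se, study_index, X) with X = intercept + requested covariates."""
        y = np.array([o.log_rr for o in self.observations], dtype=float)
        se = np.array([o.se_log_rr for o in self.observations], dtype=float)
        studies = {sid: i for i, sid in enumerate(dict.fromkeys(o.study_id for o in self.observations))}
        g = np.array([studies[o.study_id] for o in self.observations], dtype=int)
        X = np.ones((len(y), 1 + len(covariates)))
        for j, name in enumerate(covariates, start=1):
            X[:, j] = [o.covariates.get(name, 0) for o in self.observations]
        return y, se, g, X


def rr_ci_to_log(estimate: float, lower: float, upper: float) -> tuple[float, float]:
    """Convert a reported ratio estimate with 95% CI to (log_rr, se_log_rr).

    The SE uses the full interval width on the log scale,
    (log(upper) - log(lower)) / (2 * 1.96), assuming a symmetric normal
    interval on the log scale.
    """
    if estimate <= 0 or lower <= 0 or upper <= 0:
        raise ValidationError(f"ratio and CI bounds must be positive, got ({estimate}, {lower}, {upper})")
    if upper <= lower:
        raise ValidationError(f"CI upper bound must exceed lower bound, got ({lower}, {upper})")
    return math.log(estimate), (math.log(upper) - math.log(lower)) / (2 * Z_95)


def adjust_se_for_repeats(obs: EffectObservation, mode: str = "sqrt") -> EffectObservation:
    """Inflate the SE of a repeated (non-independent) measurement.

    With ``mode='sqrt'`` the SE is scaled by sqrt(n_repeats), so the k
    repeats jointly carry the inverse-variance weight of one independent
    observation; ``mode='linear'`` scales by n_repeats (more aggressive).
    """
    if mode not in ("sqrt", "linear"):
        raise ValueError(f"mode must be 'sqrt' or 'linear', got {mode!r}")
    k = obs.n_repeats
    if k == 1:
        return obs
    factor = math.sqrt(k) if mode == "sqrt" else float(k)
    return replace(obs, se_log_rr=obs.se_log_rr * factor)


def derive_testable_covariates(dataset: RiskOutcomeDataset) -> tuple[CovariateSpec, ...]:
    """Recompute testability: a covariate is testable iff both its levels
    are observed at least twice in this dataset."""
    specs = []
    for spec in dataset.covariate_specs:
        values = [o.covariates.get(spec.name, 0) for o in dataset.observations]
        n0 = values.count(0)
        n1 = values.count(1)
        specs.append(CovariateSpec(spec.name, spec.reference_level, testable=(n0 >= 2 and n1 >= 2)))
    return tuple(specs)


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    try:
        frame = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"empty or unparseable file: {path}") from exc
    except pd.errors.ParserError as exc:
        raise ValidationError(f"malformed file {path}: {exc}") from exc
    if frame.empty:
        raise ValidationError(f"no data rows in {path}")
    return frame


DEFAULT_SCHEMA = {
    "study_id": "study_id",
    "estimate": "estimate",
    "lower": "lower",
    "upper": "upper",
    "measure_type": "measure_type",  # optional column
    "n_repeats": "n_repeats",        # optional column
}


def read_extraction_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    risk_name: str = "risk",
    outcome_name: str = "outcome",
    repeat_adjustment: str | None = "sqrt",
) -> RiskOutcomeDataset:
    """Read a study extraction sheet of ratio estimates with 95% CIs.

    ``schema`` maps logical names (study_id, estimate, lower, upper and
    optionally measure_type, n_repeats) to the sheet's column names.
    Covariate columns are recognised by the ``cv_`` prefix. Estimates and
    CI bounds are converted to the log scale; when ``repeat_adjustment``
    is not None, SEs of repeated measurements are inflated after the
    conversion.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    frame = _read_delimited(path)
    required = ["study_id", "estimate", "lower", "upper"]
    missing = [schema[k] for k in required if schema[k] not in frame.columns]
    if missing:
        raise ValidationError(f"missing required column(s) {missing} in {path}")

    cov_columns = [c for c in frame.columns if c.startswith("cv_")]
    problems: list[str] = []
    observations: list[EffectObservation] = []
    for idx, row in frame.iterrows():
        est, lo, hi = (row[schema[k]] for k in ("estimate", "lower", "upper"))
        if any(pd.isna(v) for v in (est, lo, hi)):
            problems.append(f"row {idx}: missing estimate or CI bound")
            continue
        try:
            log_rr, se = rr_ci_to_log(float(est), float(lo), float(hi))
        except ValidationError as exc:
            problems.append(f"row {idx}: {exc}")
            continue
        n_rep = 1
        if schema["n_repeats"] in frame.columns and not pd.isna(row[schema["n_repeats"]]):
            n_rep = int(row[schema["n_repeats"]])
        measure = "RR"
        if schema["measure_type"] in frame.columns and not pd.isna(row[schema["measure_type"]]):
            measure = str(row[schema["measure_type"]]).upper()
        covs = {}
        for c in cov_columns:
            v = row[c]
            covs[c[3:]] = int(v) if not pd.isna(v) else 0
        try:
            obs = EffectObservation(
                study_id=str(row[schema["study_id"]]),
                log_rr=log_rr,
                se_log_rr=se,
                n_repeats=n_rep,
                covariates=covs,
                measure_type=measure,
            )
        except ValidationError as exc:
            problems.append(f"row {idx}: {exc}")
            continue
        if repeat_adjustment is not None:
            obs = adjust_se_for_repeats(obs, mode=repeat_adjustment)
        observations.append(obs)
    if problems:
        raise ValidationError("invalid extraction rows:\n" + "\n".join(problems))
    return RiskOutcomeDataset(risk_name, outcome_name, tuple(observations))


def read_canonical_table(
    path: str | Path, risk_name: str = "risk", outcome_name: str = "outcome"
) -> RiskOutcomeDataset:
    """Read the canonical (already log-scale) table written by
    :func:`write_canonical_table`."""
    frame = _read_delimited(path)
    missing = [c for c in CANONICAL_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"missing canonical column(s) {missing} in {path}")
    cov_columns = [c for c in frame.columns if c.startswith("cv_")]
    observations = tuple(
        EffectObservation(
            study_id=str(row["study_id"]),
            log_rr=float(row["log_rr"]),
            se_log_rr=float(row["se_log_rr"]),
            n_repeats=int(row["n_repeats"]),
            covariates={c[3:]: int(row[c]) for c in cov_columns},
        )
        for _, row in frame.iterrows()
    )
    return RiskOutcomeDataset(risk_name, outcome_name, observations)


def write_canonical_table(dataset: RiskOutcomeDataset, path: str | Path) -> None:
    """Write the validated dataset in canonical column order (floats at 12
    significant digits; round-trips through :func:`read_canonical_table`)."""
    frame = dataset.to_frame()
    sep = "\t" if Path(path).suffix.lower() in (".tsv", ".tab", ".txt") else ","
    frame.to_csv(path, sep=sep, index=False, float_format="%.12g")
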