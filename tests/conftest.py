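import numpy as np
import pytest

from burdenproof import EffectObservation, RiskOutcomeDataset


def make_dataset(log_rrs, ses, study_ids=None, covariates=None,
                 risk="risk", outcome="outcome"):
    """Build a small dataset from parallel lists."""
    n = len(log_rrs)
    if study_ids is None:
        study_ids = [f"s{i}" for i in range(n)]
    covariates = covariates or [{} for _ in range(n)]
    obs = tuple(
        EffectObservation(study_id=str(sid), log_rr=float(y), se_log_rr=float(se),
                          covariates=cov)
        for sid, y, se, cov in zip(study_ids, log_rrs, ses, covariates)
    )
    return RiskOutcomeDataset(risk, outcome, obs)


@pytest.fixture
def dataset_factory():
    return make_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(0)
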