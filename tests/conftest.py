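import numpy as np
import pandas as pd
import pytest

from matshare import (
    CohortMetadata,
    FeatureTable,
    SimConfig,
    simulate_cohort,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    return FeatureTable(
        feature_ids=("a", "b", "c"),
        sample_ids=("s1", "s2"),
        counts=np.array([[3, 0], [1, 2], [0, 5]]),
    )


def make_metadata(pairs, extra_mothers=(), covariates=None):
    """Build metadata from (infant_id, mother_id) links; covariates optional."""
    rows = []
    mothers = sorted({m for _, m in pairs} | set(extra_mothers))
    for m in mothers:
        rows.append(
            {"sample_id": m, "subject_id": f"S-{m}", "role": "mother", "pair_id": ""}
        )
    for i, m in pairs:
        row = {"sample_id": i, "subject_id": f"S-{i}", "role": "infant", "pair_id": m}
        if covariates and i in covariates:
            row.update(covariates[i])
        rows.append(row)
    frame = pd.DataFrame(rows)
    for col in frame.columns:
        frame[col] = frame[col].fillna("")
    return CohortMetadata(frame)


@pytest.fixture(scope="session")
def recovery_cohort():
    """Mid-size cohort with planted transmission, reused across modules."""
    config = SimConfig(n_pairs=200, tau0=0.5, tau_jitter_sd=0.05, seed=42)
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def small_cohort():
    config = SimConfig(n_pairs=25, tau0=0.3, tau_jitter_sd=0.05, seed=7)
    return simulate_cohort(config)
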