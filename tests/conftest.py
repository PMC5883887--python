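import numpy as np
import pandas as pd
import pytest

import dthazard as dt


def make_person_months(
    n_subjects: int = 60,
    n_months: int = 30,
    seed: int = 0,
    event_rate: float = 0.01,
    n_clusters: int = 10,
    weighted: bool = True,
) -> pd.DataFrame:
    """Small random person-month array with realistic structure, built by a
    per-subject loop independent of the package's expansion code."""
    rng = np.random.default_rng(seed)
    rows = []
    for sid in range(n_subjects):
        w = rng.lognormal(0, 0.4) if weighted else 1.0
        cluster = sid % n_clusters
        s = rng.standard_normal()
        horizon = int(rng.integers(5, n_months + 1))
        for m in range(horizon):
            a = 0.5 * s + np.sqrt(1 - 0.25) * rng.standard_normal()
            event = int(rng.random() < event_rate * (1 + 0.5 * a + 0.3 * s))
            rows.append(
                dict(subject_id=sid, month=m, score_A=a, score_S=s,
                     event=event, weight=w, cluster_id=cluster)
            )
            if event:
                break
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def pm_fixture() -> pd.DataFrame:
    """~1,400-row person-month array with events, weights and 10 clusters."""
    return make_person_months(n_subjects=60, n_months=30, seed=42, event_rate=0.02)


@pytest.fixture(scope="session")
def small_cohort() -> dt.Cohort:
    """A simulated 800-subject cohort with a raised hazard so tests see
    enough events."""
    config = dt.SimConfig(
        n_subjects=800,
        cluster_size_range=(20, 40),
        weight_sd=0.3,
        lambda_S=0.6,
        lambda_A_start=0.5,
        lambda_A_end=0.3,
        ar_phi=0.4,
        alpha_base=-4.3,
        training_offset=-1.0,
        training_months=3,
        beta_A=0.5,
        beta_S=0.4,
        admin_cutoff_range=(26, 30),
        seed=99,
    )
    return dt.simulate(config)


@pytest.fixture(scope="session")
def small_array(small_cohort) -> pd.DataFrame:
    arr = dt.expand_to_person_months(small_cohort.subjects, small_cohort.scores)
    return dt.standardize_scores(arr)
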