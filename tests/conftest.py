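import numpy as np
import pandas as pd
import pytest

from cogtraj.synthetic import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-subject synthetic cohort with default artifact rates."""
    cfg = SimulationConfig(n_subjects=400, seed=42)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_cohort():
    """A 500-subject artifact-free cohort plus its analysis tables."""
    from cogtraj.preprocess import make_analysis_cohort

    cfg = SimulationConfig(
        n_subjects=500,
        seed=7,
        reduced_denominator_rate=0.0,
        low_denominator_rate=0.0,
        same_day_duplicate_rate=0.0,
    )
    cohort = generate_cohort(cfg)
    clean, profiles, report = make_analysis_cohort(
        cohort.scores, cohort.demographics, cohort.prescriptions, cohort.honos
    )
    return cohort, clean, profiles, report


def two_cluster_scores(n_per=40, hi=30.0, lo=0.0, n_visits=4):
    """Two noise-free constant-score groups: a separable-cluster oracle."""
    rows = []
    for i in range(n_per):
        for t in np.linspace(0, 2, n_visits):
            rows.append((f"H{i}", t, hi))
            rows.append((f"L{i}", t, lo))
    return pd.DataFrame(rows, columns=["subject_id", "time_years", "weighted_score"])
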