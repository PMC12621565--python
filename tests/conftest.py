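import numpy as np
import pytest

from synthtte import aggdata


@pytest.fixture
def small_table() -> aggdata.AggregateTrialTable:
    """Deterministic 2-trial x 3-arm fixture with small-to-medium arms."""
    return aggdata.generate_fixture(
        aggdata.FixtureConfig(n_trials=2, arms_per_trial=3, n_range=(40, 400), seed=7)
    )


@pytest.fixture
def large_arm() -> aggdata.ArmSummary:
    """A confirmatory-scale arm mirroring published phase-III aggregates."""
    corr = np.array([
        [1.00, 0.10, 0.05, 0.12],
        [0.10, 1.00, 0.85, 0.05],
        [0.05, 0.85, 1.00, 0.02],
        [0.12, 0.05, 0.02, 1.00],
    ])
    weeks = [4, 8, 12, 20, 28, 36, 52, 68]
    means = [-5.6, -8.8, -12.0, -15.5, -17.7, -19.0, -20.0, -20.4]
    n = 2108
    return aggdata.ArmSummary(
        trial_id="T-OB", arm_id="T-OB-ACT", treatment="combo", dose=2.4,
        route="sc_weekly", n=n, duration=68.0,
        baseline_means={"age": 47.0, "bmi": 37.9, "weight": 106.9, "hba1c": 5.5},
        baseline_sds={"age": 11.8, "bmi": 6.7, "weight": 21.0, "hba1c": 0.4},
        baseline_corr=corr,
        visits=[aggdata.VisitSummary(week=w, mean_change=m, se=9.0 / np.sqrt(n))
                for w, m in zip(weeks, means)],
        responder_rates={5.0: 1937 / n, 10.0: 1760 / n, 15.0: 1391 / n},
        ae_rates={"gi": 0.796},
        discontinuation_rate=0.059,
    )
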