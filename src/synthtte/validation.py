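"""Predictive-validity tooling.

Leave-trial-out (LTO) cross-validation with calibration metrics, posterior
predictive checks (PPC), and simulation-based calibration (SBC).

Calibration regresses *observed on predicted*: slope 1 and intercept 0 mean
perfect calibration; slope < 1 means the model under-predicts outcome
magnitudes, and 1/slope is the factor by which downstream sample-size
calculations based on the predictions should be inflated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats

from .aggdata import AggregateTrialTable, ArmSummary

__all__ = [
    "CalibrationReport",
    "PPCReport",
    "SBCReport",
    "calibration_regression",
    "leave_trial_out",
    "inflation_factor",
    "posterior_predictive_check",
    "sbc",
]


@dataclass
class CalibrationReport:
    rmse: float
    slope: float
    intercept: float
    r2: float
    slope_ci95: tuple[float, float] | None
    intercept_ci95: tuple[float, float] | None
    n_heldout: int
    failed_folds: list[str] = field(default_factory=list)
    degenerate: bool = False

    @property
    def inflation_factor(self) -> float:
        return inflation_factor(self)


@dataclass
class PPCReport:
    coverage_fraction: float
    expected_coverage: float
    n: int
    tolerance: float
    passed: bool


@dataclass
class SBCReport:
    ranks: dict[str, np.ndarray]
    ks_p: dict[str, float]
    n_draws: int
    pass_threshold: float = 0.15

    @property
    def passed(self) -> bool:
        return all(p > self.pass_threshold for p in self.ks_p.values())


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def calibration_regression(observed, predicted) -> CalibrationReport:
    """OLS of observed on predicted plus RMSE of the raw predictions."""
    y = np.asarray(observed, dtype=float)
    x = np.asarray(predicted, dtype=float)
    if len(y) != len(x) or len(y) < 2:
        raise ValueError("need >= 2 observation/prediction pairs")
    rmse = float(np.sqrt(np.mean((y - x) ** 2)))
    if np.ptp(x) == 0:
        return CalibrationReport(rmse=rmse, slope=0.0, intercept=float(y.mean()),
                                 r2=0.0, slope_ci95=None, intercept_ci95=None,
                                 n_heldout=len(y), degenerate=True)
    res = stats.linregress(x, y)
    n = len(y)
    tcrit = stats.t.ppf(0.975, n - 2) if n > 2 else float("inf")
    return CalibrationReport(
        rmse=rmse,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        slope_ci95=(res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr),
        intercept_ci95=(res.intercept - tcrit * res.intercept_stderr,
                        res.intercept + tcrit * res.intercept_stderr),
        n_heldout=n,
    )


def leave_trial_out(
    table: AggregateTrialTable,
    model: Callable[[list[ArmSummary], ArmSummary], float],
    endpoint: Callable[[ArmSummary], float | None],
    by_trial: bool = False,
) -> CalibrationReport:
    """Leave-one-out calibration across arms (or whole trials).

    ``endpoint(arm)`` extracts the observed quantity (None = arm lacks the
    endpoint and is skipped); ``model(train_arms, held_out_arm)`` returns a
    prediction fit without the held-out unit.  A fold whose model call
    raises is flagged and excluded rather than aborting the run.
    """
    arms = [a for a in table.arms if endpoint(a) is not None]
    if len(arms) < 3:
        raise ValueError("need >= 3 arms carrying the endpoint")
    obs, pred, failed = [], [], []
    for arm in arms:
        if by_trial:
            train = [a for a in arms if a.trial_id != arm.trial_id]
        else:
            train = [a for a in arms if (a.trial_id, a.arm_id) != (arm.trial_id, arm.arm_id)]
        try:
            yhat = model(train, arm)
        except Exception:
            failed.append(arm.arm_id)
            continue
        obs.append(endpoint(arm))
        pred.append(yhat)
    if len(obs) < 2:
        raise ValueError("fewer than 2 successful folds")
    report = calibration_regression(obs, pred)
    report.failed_folds = failed
    return report


def inflation_factor(report: CalibrationReport) -> float:
    """1/slope: multiplier for prediction-based sample-size calculations."""
    if report.slope <= 0:
        raise ValueError(f"inflation factor undefined for slope {report.slope}")
    return 1.0 / report.slope


# ---------------------------------------------------------------------------
# Posterior predictive checks
# ---------------------------------------------------------------------------

def posterior_predictive_check(
    observed, bands, expected_coverage: float = 0.90, tolerance: float = 0.03
) -> PPCReport:
    """Fraction of observations inside per-observation (lo, hi) predictive bands."""
    y = np.asarray(observed, dtype=float)
    b = np.asarray(bands, dtype=float)
    if y.size == 0:
        raise ValueError("no observations")
    if b.shape != (len(y), 2):
        raise ValueError(f"bands must be (n, 2), got {b.shape}")
    if np.any(b[:, 0] > b[:, 1]):
        raise ValueError("band lower bound exceeds upper bound")
    inside = (y >= b[:, 0]) & (y <= b[:, 1])
    cov = float(inside.mean())
    return PPCReport(coverage_fraction=cov, expected_coverage=expected_coverage,
                     n=len(y), tolerance=tolerance,
                     passed=abs(cov - expected_coverage) <= tolerance)


# ---------------------------------------------------------------------------
# Simulation-based calibration
# ---------------------------------------------------------------------------

def sbc(
    prior_sampler: Callable[[np.random.Generator], dict[str, float]],
    simulator: Callable[[dict[str, float], np.random.Generator], object],
    posterior_sampler: Callable[[object, int, np.random.Generator], dict[str, np.ndarray]],
    n_runs: int = 100,
    n_draws: int = 100,
    seed: int = 0,
) -> SBCReport:
    """Rank-statistic calibration check for a posterior approximation.

    For each run: draw θ ~ prior, simulate data | θ, draw L posterior
    samples, record the rank of θ among them per parameter.  If the
    posterior is exact the ranks are uniform on {0..L}; uniformity is
    tested per parameter by a Kolmogorov-Smirnov test on the
    midpoint-continuity-corrected ranks (r + ½)/(L + 1).
    """
    if n_runs < 1 or n_draws < 1:
        raise ValueError("n_runs and n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    ranks: dict[str, list[int]] = {}
    for _ in range(n_runs):
        theta = prior_sampler(rng)
        data = simulator(theta, rng)
        draws = posterior_sampler(data, n_draws, rng)
        if set(draws) != set(theta):
            raise ValueError(
                f"posterior sampler parameters {sorted(draws)} != prior's {sorted(theta)}")
        for name, value in theta.items():
            d = np.asarray(draws[name], dtype=float)
            if len(d) != n_draws:
                raise ValueError(
                    f"posterior sampler returned {len(d)} draws for {name!r}, "
                    f"expected {n_draws}")
            ranks.setdefault(name, []).append(int(np.sum(d < value)))
    report_ranks = {k: np.asarray(v) for k, v in ranks.items()}
    ks_p = {}
    for name, r in report_ranks.items():
        u = (r + 0.5) / (n_draws + 1.0)
        ks_p[name] = float(stats.kstest(u, "uniform").pvalue)
    return SBCReport(ranks=report_ranks, ks_p=ks_p, n_draws=n_draws)
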