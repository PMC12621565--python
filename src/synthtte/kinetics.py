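"""Longitudinal weight-loss kinetics and time-to-event analyses.

The mean weight-loss trajectory of incretin/amylin pharmacotherapy follows
an exponential approach to plateau,

    W(t) = W_inf · (1 − e^{−k t}),

with W_inf the asymptotic loss magnitude (pp) and k a per-week rate
constant; velocity profiles are finite differences of the visit means, and
time-to-threshold inverts the plateau model in closed form.  Patient-level
time-to-response (first visit reaching a loss threshold) is analysed with
Kaplan-Meier methods (dropout = right-censoring), log-rank tests with
optional Bonferroni adjustment for pairwise multiplicity, competing-risks
cumulative incidence via Aalen-Johansen, and number-needed-to-harm for
adverse-event excesses.

Sign convention: losses arrive as negative percentage points; magnitudes
are used internally for the plateau fit and thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from lifelines import AalenJohansenFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import optimize

from .sipd import SyntheticCohort

__all__ = [
    "PlateauModel",
    "VelocityProfile",
    "KMCurve",
    "fit_plateau",
    "time_to_threshold",
    "velocity_profile",
    "response_times",
    "km_time_to_response",
    "logrank",
    "nnh",
    "competing_risks_cif",
]

#: |velocity| below this (pp/week) declares the trajectory plateaued.
PLATEAU_VELOCITY_EPS = 0.05


@dataclass
class PlateauModel:
    w_final: float                      # asymptotic loss magnitude, pp > 0
    k: float                            # per-week rate constant > 0
    fitted_visits: dict[float, float] = field(default_factory=dict)
    residual_rmse: float = 0.0

    def predict_magnitude(self, t):
        return self.w_final * (1.0 - np.exp(-self.k * np.asarray(t, dtype=float)))


@dataclass
class VelocityProfile:
    intervals: list[tuple[float, float]]
    velocities: list[float]             # pp/week, loss magnitudes
    max_velocity: float
    max_interval: tuple[float, float]
    plateau_interval: tuple[float, float] | None = None


@dataclass
class KMCurve:
    times: np.ndarray
    survival: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    median: float | None


# ---------------------------------------------------------------------------
# Plateau kinetics
# ---------------------------------------------------------------------------

def fit_plateau(visits: dict[float, float]) -> PlateauModel:
    """Nonlinear least squares of W(t) = W_inf·(1 − e^{−kt}) to visit means.

    ``visits`` maps week -> mean change (negative = loss); the model is fit
    on loss magnitudes.
    """
    if len(visits) < 3:
        raise ValueError("need >= 3 visits")
    t = np.array(sorted(visits))
    y = -np.array([visits[w] for w in t])   # magnitudes

    w0 = max(y.max(), 1e-6)
    k0 = 0.05

    def resid(theta):
        w_inf, log_k = theta
        return w_inf * (1.0 - np.exp(-math.exp(log_k) * t)) - y

    sol = optimize.least_squares(resid, [w0, math.log(k0)], method="lm", max_nfev=20000)
    if not sol.success:
        raise RuntimeError(f"plateau fit did not converge: {sol.message}")
    w_inf, log_k = sol.x
    k = math.exp(log_k)
    fitted = w_inf * (1.0 - np.exp(-k * t))
    rmse = float(np.sqrt(np.mean((fitted - y) ** 2)))
    return PlateauModel(w_final=float(w_inf), k=float(k),
                        fitted_visits={float(w): float(-f) for w, f in zip(t, fitted)},
                        residual_rmse=rmse)


def time_to_threshold(model: PlateauModel, x: float) -> float:
    """Week at which the fitted loss magnitude first reaches ``x`` pp.

    Closed form t = −ln(1 − x/W_inf)/k; raises when the threshold exceeds
    the asymptote (never reached).
    """
    if not (0.0 < x):
        raise ValueError("threshold must be > 0")
    if x >= model.w_final:
        raise ValueError(
            f"threshold {x} pp is unreachable (asymptote {model.w_final:.3g} pp)")
    return -math.log(1.0 - x / model.w_final) / model.k


def velocity_profile(visits: dict[float, float]) -> VelocityProfile:
    """Per-interval loss velocity (pp/week) between adjacent visits."""
    if len(visits) < 2:
        raise ValueError("need >= 2 visits")
    weeks = sorted(visits)
    if len(set(weeks)) != len(weeks):
        raise ValueError("duplicate visit weeks")
    y = [-visits[w] for w in weeks]
    intervals, velocities = [], []
    for (w1, y1), (w2, y2) in zip(zip(weeks, y), zip(weeks[1:], y[1:])):
        intervals.append((w1, w2))
        velocities.append((y2 - y1) / (w2 - w1))
    i_max = int(np.argmax(velocities))
    plateau = next((iv for iv, v in zip(intervals, velocities)
                    if abs(v) < PLATEAU_VELOCITY_EPS), None)
    return VelocityProfile(intervals=intervals, velocities=velocities,
                           max_velocity=float(velocities[i_max]),
                           max_interval=intervals[i_max],
                           plateau_interval=plateau)


# ---------------------------------------------------------------------------
# Time-to-response
# ---------------------------------------------------------------------------

def response_times(
    cohort: SyntheticCohort, threshold: float, interpolate: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """(time, event) pairs: first week reaching ``threshold`` pp loss.

    Default is the first *scheduled* visit at/after the crossing; with
    ``interpolate`` the crossing week is linearly interpolated between the
    bracketing visits.  Patients never reaching the threshold are censored
    at their last observed week (dropout or end of follow-up).
    """
    times, events = [], []
    for rec in cohort.records:
        if not rec.trajectory:
            continue
        weeks = sorted(rec.trajectory)
        losses = [-rec.trajectory[w] for w in weeks]
        hit = next((j for j, v in enumerate(losses) if v >= threshold), None)
        if hit is None:
            times.append(weeks[-1] if rec.dropout_week is None else rec.dropout_week)
            events.append(0)
        elif interpolate and hit > 0:
            w1, w2 = weeks[hit - 1], weeks[hit]
            y1, y2 = losses[hit - 1], losses[hit]
            frac = (threshold - y1) / (y2 - y1) if y2 != y1 else 1.0
            times.append(w1 + frac * (w2 - w1))
            events.append(1)
        else:
            times.append(weeks[hit])
            events.append(1)
    if not times:
        raise ValueError("empty cohort (no observed trajectories)")
    return np.asarray(times, dtype=float), np.asarray(events, dtype=int)


def km_time_to_response(
    cohort: SyntheticCohort, threshold: float, interpolate: bool = False
) -> KMCurve:
    """Product-limit estimate of time to reaching a weight-loss threshold."""
    t, e = response_times(cohort, threshold, interpolate)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    ci = kmf.confidence_interval_survival_function_
    times = sf.index.to_numpy(dtype=float)
    ev = kmf.event_table["observed"].to_numpy()
    at_risk = kmf.event_table["at_risk"].to_numpy()
    surv = sf.iloc[:, 0].to_numpy()
    # first time survival drops to <= 0.5 (tolerance absorbs product-limit
    # rounding when the step lands exactly on one half)
    below = np.flatnonzero(surv <= 0.5 + 1e-9)
    med = float(times[below[0]]) if below.size else None
    return KMCurve(
        times=times,
        survival=surv,
        ci_lo=ci.iloc[:, 0].to_numpy(),
        ci_hi=ci.iloc[:, 1].to_numpy(),
        at_risk=at_risk,
        events=ev,
        median=med,
    )


def logrank(
    groups: list[tuple[np.ndarray, np.ndarray]], alpha: float = 0.05,
    alpha_adjust: str = "none",
) -> dict[str, float]:
    """Log-rank test across groups of (times, events) arrays.

    ``alpha_adjust='bonferroni'`` reports the pairwise-adjusted level
    alpha / C(k, 2) alongside the omnibus statistic.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for g, (t, e) in enumerate(groups):
        if len(t) == 0:
            raise ValueError(f"group {g} has zero subjects")
    times = np.concatenate([t for t, _ in groups])
    events = np.concatenate([e for _, e in groups])
    labels = np.concatenate([np.full(len(t), i) for i, (t, _) in enumerate(groups)])
    res = multivariate_logrank_test(times, labels, events)
    k = len(groups)
    adj = alpha if alpha_adjust == "none" else alpha / (k * (k - 1) / 2)
    return {"chi2": float(res.test_statistic), "p": float(res.p_value),
            "df": k - 1, "adjusted_alpha": float(adj)}


def nnh(p_treat: float, p_control: float) -> float:
    """Number needed to harm: 1/(p_treat − p_control), for an AE excess."""
    if p_treat <= p_control:
        raise ValueError(
            f"no excess harm: p_treat {p_treat} <= p_control {p_control}")
    return 1.0 / (p_treat - p_control)


def competing_risks_cif(
    times: np.ndarray, event_types: np.ndarray, event_of_interest: int
) -> tuple[np.ndarray, np.ndarray]:
    """Aalen-Johansen cumulative incidence for one of two competing events.

    ``event_types``: 0 = censored, 1/2 = the two competing event kinds.
    Returns (times, CIF) for ``event_of_interest``.
    """
    ajf = AalenJohansenFitter(calculate_variance=False)
    ajf.fit(np.asarray(times, dtype=float), np.asarray(event_types),
            event_of_interest=event_of_interest)
    cif = ajf.cumulative_density_
    return cif.index.to_numpy(dtype=float), cif.iloc[:, 0].to_numpy()
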