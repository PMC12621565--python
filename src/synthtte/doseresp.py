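"""Dose-response modelling: efficacy Emax, tolerability logit-Emax,
ED-quantiles, exposure-response, and benefit-risk frontiers.

Efficacy follows the saturating Emax form

    E(d) = Emax · d^h / (ED50^h + d^h),

hyperbolic when the Hill coefficient h is fixed at 1.  Tolerability
endpoints (GI adverse events, discontinuation) are modelled on the log-odds
scale, anchored at a baseline rate:

    logit P(AE | d) = logit(p_baseline) + Emax_tol · d / (ED50_tol + d).

The tolerability fit is a penalized binomial likelihood whose penalties are
weakly-informative priors, Emax_tol ~ N(0, 2.5) and
log(ED50_tol) ~ N(log 10, 1); a seeded Laplace-approximation draw generator
provides posterior-style uncertainty summaries without MCMC.

The benefit-risk frontier evaluates the efficacy and tolerability curves on
a common dose grid and finds where tolerability decision gates
(discontinuation <= 20 %, GI-AE <= 75 % by default) cross the fitted
curves, yielding a therapeutic dose window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "EmaxFit",
    "LogitEmaxFit",
    "FrontierPoint",
    "TherapeuticWindow",
    "ExposureResponseFit",
    "IdentifiabilityError",
    "SeparationError",
    "emax_curve",
    "fit_emax",
    "ed_quantile",
    "logit_within_arm_variance",
    "fit_logit_emax",
    "logit_emax_prob",
    "build_frontier",
    "fit_exposure_response",
]

DEFAULT_GATES = {"discontinuation": 0.20, "gi_ae": 0.75}

#: Penalty/prior hyperparameters for the tolerability fit.
PRIOR_EMAX_TOL_SD = 2.5
PRIOR_LOG_ED50_MEAN = math.log(10.0)
PRIOR_LOG_ED50_SD = 1.0


class IdentifiabilityError(ValueError):
    """Fewer distinct doses than free parameters."""


class SeparationError(ValueError):
    """Event counts carry no information (all zero or all n)."""


def _logit(p):
    return np.log(p / (1 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# Efficacy Emax
# ---------------------------------------------------------------------------

@dataclass
class EmaxFit:
    emax: float
    ed50: float
    hill: float = 1.0
    ci_emax: tuple[float, float] | None = None
    ci_ed50: tuple[float, float] | None = None
    fit_stats: dict[str, float] = field(default_factory=dict)

    def predict(self, dose):
        return emax_curve(np.asarray(dose, dtype=float), self.emax, self.ed50, self.hill)


def emax_curve(dose, emax: float, ed50: float, hill: float = 1.0):
    """E(d) = Emax·d^h/(ED50^h + d^h); zero effect at dose 0."""
    d = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        dh = np.where(d > 0, d**hill, 0.0)
    return emax * dh / (ed50**hill + dh)


def fit_emax(doses, responses, ns=None, hill_mode: str = "fixed_1") -> EmaxFit:
    """Weighted nonlinear least-squares Emax fit to arm-level mean responses.

    ``ns`` act as weights (variance ∝ 1/n).  ``hill_mode`` is ``fixed_1``
    (hyperbolic) or ``estimated`` (sigmoid).  Fit statistics include R²,
    adjusted R², RMSE, AIC/BIC (Gaussian likelihood), and a pure-error
    lack-of-fit F-test p-value when doses are replicated.
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    w = np.ones_like(y) if ns is None else np.sqrt(np.asarray(ns, dtype=float))
    n_distinct = len(np.unique(d))
    n_par = 2 if hill_mode == "fixed_1" else 3
    if n_distinct < n_par + 1:
        raise IdentifiabilityError(
            f"{n_distinct} distinct doses cannot identify {n_par} parameters")

    scale = np.max(np.abs(y)) or 1.0
    sign = 1.0 if y[np.argmax(np.abs(y))] >= 0 else -1.0

    def resid(theta):
        if hill_mode == "fixed_1":
            emax, log_ed50 = theta
            h = 1.0
        else:
            emax, log_ed50, h = theta
        return w * (emax_curve(d, emax, math.exp(log_ed50), h) - y)

    x0 = [sign * scale, math.log(max(np.median(d[d > 0]), 1e-3))]
    if hill_mode != "fixed_1":
        x0.append(1.0)
    sol = optimize.least_squares(resid, x0, method="lm", max_nfev=10000)
    if hill_mode == "fixed_1":
        emax, log_ed50 = sol.x
        hill = 1.0
    else:
        emax, log_ed50, hill = sol.x
    ed50 = math.exp(log_ed50)

    yhat = emax_curve(d, emax, ed50, hill)
    res = y - yhat
    nobs = len(y)
    ss_res = float(np.sum((w * res) ** 2))
    ss_tot = float(np.sum((w * (y - np.average(y, weights=w**2))) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    dof = max(nobs - n_par, 1)
    rmse = math.sqrt(np.sum(res**2) / nobs)
    sigma2 = ss_res / nobs if ss_res > 0 else 1e-300
    ll = -0.5 * nobs * (math.log(2 * math.pi * sigma2) + 1)
    stats_d = {
        "r2": max(0.0, min(1.0, r2)),
        "adj_r2": 1.0 - (1.0 - r2) * (nobs - 1) / dof,
        "rmse": rmse,
        "aic": 2 * n_par - 2 * ll,
        "bic": n_par * math.log(nobs) - 2 * ll,
        "lack_of_fit_p": _lack_of_fit_p(d, y, yhat, n_par),
    }

    # Wald CIs from the Gauss-Newton covariance, via the jacobian at optimum
    ci_emax = ci_ed50 = None
    try:
        j = sol.jac
        cov = np.linalg.inv(j.T @ j) * (ss_res / dof)
        se = np.sqrt(np.diag(cov))
        tcrit = stats.t.ppf(0.975, dof)
        ci_emax = (emax - tcrit * se[0], emax + tcrit * se[0])
        lo, hi = log_ed50 - tcrit * se[1], log_ed50 + tcrit * se[1]
        ci_ed50 = (math.exp(lo), math.exp(hi))
    except np.linalg.LinAlgError:
        pass
    return EmaxFit(emax=float(emax), ed50=float(ed50), hill=float(hill),
                   ci_emax=ci_emax, ci_ed50=ci_ed50, fit_stats=stats_d)


def _lack_of_fit_p(d, y, yhat, n_par) -> float:
    """Pure-error F-test against the saturated dose-means model.

    Defined only when some dose level is replicated; otherwise NaN.
    """
    levels, inv = np.unique(d, return_inverse=True)
    n, k = len(y), len(levels)
    if n <= k or k <= n_par:
        return float("nan")
    group_means = np.array([y[inv == g].mean() for g in range(k)])
    ss_pe = float(np.sum((y - group_means[inv]) ** 2))
    ss_lof = float(np.sum((group_means[inv] - yhat) ** 2))
    df_pe, df_lof = n - k, k - n_par
    if ss_pe <= 0 or df_lof <= 0:
        return float("nan")
    f = (ss_lof / df_lof) / (ss_pe / df_pe)
    return float(stats.f.sf(f, df_lof, df_pe))


def ed_quantile(fit: EmaxFit | float, p: float, hill: float | None = None) -> float:
    """Dose producing p % of the maximal effect: ED_p = ED50·(p/(100−p))^(1/h).

    Accepts an :class:`EmaxFit` or a bare ED50 (with ``hill``).
    """
    if not (0.0 < p < 100.0):
        raise ValueError(f"p must lie in (0, 100), got {p}")
    if isinstance(fit, EmaxFit):
        ed50, h = fit.ed50, fit.hill
    else:
        ed50, h = float(fit), 1.0 if hill is None else hill
    return ed50 * (p / (100.0 - p)) ** (1.0 / h)


# ---------------------------------------------------------------------------
# Tolerability logit-Emax
# ---------------------------------------------------------------------------

@dataclass
class LogitEmaxFit:
    p_baseline: float
    emax_tol: float
    ed50_tol: float
    endpoint: str = ""
    draws: np.ndarray | None = None     # columns: logit(p_b), emax_tol, log(ed50)
    convergence: dict[str, float | None] = field(default_factory=dict)

    def predict(self, dose):
        return logit_emax_prob(dose, self.p_baseline, self.emax_tol, self.ed50_tol)


def logit_emax_prob(dose, p_baseline: float, emax_tol: float, ed50_tol: float):
    d = np.asarray(dose, dtype=float)
    eta = _logit(p_baseline) + emax_tol * d / (ed50_tol + d)
    return _expit(eta)


def logit_within_arm_variance(n: int, p: float, continuity: bool = True) -> float:
    """Within-arm variance of a logit-transformed proportion: 1/(n·p·(1−p)).

    Degenerate proportions (0 or 1) get a continuity correction
    (x + ½)/(n + 1) when ``continuity`` is true, else raise.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if p <= 0.0 or p >= 1.0:
        if not continuity:
            raise ValueError(f"p = {p} needs a continuity correction")
        x = p * n
        p = (x + 0.5) / (n + 1.0)
    return 1.0 / (n * p * (1.0 - p))


def fit_logit_emax(doses, event_counts, ns, endpoint: str = "",
                   seed: int | None = None, n_draws: int = 2000) -> LogitEmaxFit:
    """Penalized-likelihood logit-Emax fit to dose-level event counts.

    Maximizes the binomial log-likelihood plus log-priors
    Emax_tol ~ N(0, 2.5) and log ED50_tol ~ N(log 10, 1); the baseline
    log-odds carries a diffuse N(0, 10²) penalty for numerical stability.
    Passing ``seed`` additionally draws from the Laplace (normal)
    approximation at the mode, for interval summaries.
    """
    d = np.asarray(doses, dtype=float)
    x = np.asarray(event_counts, dtype=float)
    n = np.asarray(ns, dtype=float)
    if len(np.unique(d)) < 3:
        raise IdentifiabilityError("need >= 3 dose levels")
    if np.all(x == 0) or np.all(x == n):
        raise SeparationError("event counts carry no information (all 0 or all n)")

    def neg_log_post(theta):
        eta0, emax_t, log_ed50 = theta
        eta = eta0 + emax_t * d / (math.exp(log_ed50) + d)
        # binomial loglik via log1p-exp for stability
        ll = np.sum(x * eta - n * np.logaddexp(0.0, eta))
        pen = (emax_t**2 / (2 * PRIOR_EMAX_TOL_SD**2)
               + (log_ed50 - PRIOR_LOG_ED50_MEAN) ** 2 / (2 * PRIOR_LOG_ED50_SD**2)
               + eta0**2 / (2 * 10.0**2))
        return -(ll) + pen

    p_pool = np.clip(x.sum() / n.sum(), 1e-4, 1 - 1e-4)
    x0 = np.array([_logit(p_pool), 1.0, PRIOR_LOG_ED50_MEAN])
    sol = optimize.minimize(neg_log_post, x0, method="BFGS",
                            options={"maxiter": 2000, "gtol": 1e-10})
    eta0, emax_t, log_ed50 = sol.x

    draws = None
    if seed is not None:
        h = _numerical_hessian(neg_log_post, sol.x)
        try:
            cov = np.linalg.inv(h)
            cov = (cov + cov.T) / 2
            rng = np.random.default_rng(seed)
            draws = rng.multivariate_normal(sol.x, cov, size=n_draws, method="svd")
        except np.linalg.LinAlgError:
            draws = None
    return LogitEmaxFit(
        p_baseline=float(_expit(eta0)),
        emax_tol=float(emax_t),
        ed50_tol=float(math.exp(log_ed50)),
        endpoint=endpoint,
        draws=draws,
        convergence={"rhat_max": None, "min_ess": None,
                     "optimizer_converged": float(sol.success)},
    )


def _numerical_hessian(f, x, eps: float = 1e-5) -> np.ndarray:
    k = len(x)
    h = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = eps
            ej = np.zeros(k); ej[j] = eps
            h[i, j] = h[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * eps * eps)
    return h


# ---------------------------------------------------------------------------
# Benefit-risk frontier
# ---------------------------------------------------------------------------

@dataclass
class FrontierPoint:
    dose: float
    efficacy: float
    p_discontinuation: float
    p_gi_ae: float


@dataclass
class TherapeuticWindow:
    lower: float
    upper: float
    binding_constraints: list[dict] = field(default_factory=list)
    upper_censored: bool = False   # no gate crossed on the grid


def build_frontier(
    eff: EmaxFit,
    tol_disc: LogitEmaxFit,
    tol_gi: LogitEmaxFit,
    grid: np.ndarray | None = None,
    gates: dict[str, float] | None = None,
    window_fraction: float = 80.0,
) -> tuple[list[FrontierPoint], TherapeuticWindow]:
    """Joint efficacy/tolerability frontier and therapeutic window.

    The window's lower bound is the dose achieving ``window_fraction`` % of
    Emax; its upper bound is the tightest dose at which a tolerability gate
    is crossed (root-finding on the fitted curve), or the grid maximum,
    flagged, when no gate is crossed.
    """
    if grid is None:
        grid = np.arange(0.0, 60.0 + 1e-9, 0.1)
    grid = np.asarray(grid, dtype=float)
    gates = dict(DEFAULT_GATES if gates is None else gates)

    points = [
        FrontierPoint(dose=float(d0),
                      efficacy=float(eff.predict(d0)),
                      p_discontinuation=float(tol_disc.predict(d0)),
                      p_gi_ae=float(tol_gi.predict(d0)))
        for d0 in grid
    ]

    binding = []
    crossings = []
    for name, fit in (("discontinuation", tol_disc), ("gi_ae", tol_gi)):
        thr = gates.get(name)
        if thr is None:
            continue
        f = lambda d0, fit=fit, thr=thr: float(fit.predict(d0)) - thr
        lo, hi = grid[0], grid[-1]
        if f(lo) >= 0:          # gate already exceeded at dose 0
            crossing = lo
        elif f(hi) < 0:         # never crossed
            crossing = None
        else:
            crossing = float(optimize.brentq(f, lo, hi, xtol=1e-10))
        binding.append({"name": name, "threshold": thr, "crossing_dose": crossing})
        if crossing is not None:
            crossings.append(crossing)

    lower = ed_quantile(eff, window_fraction)
    censored = not crossings
    upper = min(crossings) if crossings else float(grid[-1])
    window = TherapeuticWindow(lower=float(min(lower, upper)), upper=float(upper),
                               binding_constraints=binding, upper_censored=censored)
    return points, window


# ---------------------------------------------------------------------------
# Exposure-response
# ---------------------------------------------------------------------------

@dataclass
class ExposureResponseFit:
    slope_per_100: float
    intercept: float
    r2: float
    p_value: float
    flagged: bool = False


def fit_exposure_response(aucs, responses) -> ExposureResponseFit:
    """OLS of response on exposure; slope reported per 100 exposure units."""
    x = np.asarray(aucs, dtype=float)
    y = np.asarray(responses, dtype=float)
    if len(x) < 2:
        raise ValueError("need >= 2 points")
    if np.ptp(x) == 0:
        raise ValueError("constant exposure: design matrix rank-deficient")
    res = stats.linregress(x, y)
    flagged = len(x) == 2 or not np.isfinite(res.pvalue)
    return ExposureResponseFit(
        slope_per_100=float(res.slope * 100.0),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p_value=float(res.pvalue),
        flagged=flagged,
    )
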