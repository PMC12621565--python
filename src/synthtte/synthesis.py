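"""Cross-trial evidence synthesis.

Placebo-anchored indirect contrasts, SUCRA treatment rankings,
DerSimonian-Laird heterogeneity (with Q-profile confidence intervals),
meta-analytic-predictive (MAP) intervals on the logit scale, pooled effect
summaries, correlation meta-regression, Mahalanobis transport weights for
re-calibrating estimates to a target population, and E-values for
unmeasured confounding.

Placebo-anchored indirect comparison: with arm-vs-placebo effects
ETD_a ± se_a and ETD_b ± se_b from different trials, the indirect contrast
is ETD_a − ETD_b with standard error sqrt(se_a² + se_b²) (independent
trials).  Weight-loss effects are negative percentage points, so a more
negative contrast favours the first treatment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "EffectEstimate",
    "ContrastResult",
    "HeterogeneityEstimate",
    "MAPInterval",
    "PooledSummary",
    "indirect_contrast",
    "sucra",
    "dl_heterogeneity",
    "map_predictive_interval",
    "pooled_summary",
    "meta_regression_corr",
    "transport_weights",
    "e_value",
]


def _logit(p):
    return math.log(p / (1 - p))


def _expit(x):
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectEstimate:
    """Arm-vs-placebo estimated treatment difference (pp) with its SE."""

    label: str
    etd: float
    se: float
    n: int = 1
    population: str = "obesity"
    follow_up: float = 0.0

    def __post_init__(self):
        if not self.se > 0:
            raise ValueError(f"{self.label}: SE must be > 0")
        if self.n < 1:
            raise ValueError(f"{self.label}: n must be >= 1")


@dataclass
class ContrastResult:
    difference: float
    se_diff: float
    ci95: tuple[float, float]
    z: float
    p_value: float
    p_superiority: float
    p_noninferiority: dict[float, float] = field(default_factory=dict)
    cohens_d: float | None = None


@dataclass
class HeterogeneityEstimate:
    tau2: float
    i2_dl: float
    q: float
    df: int
    ci_tau2: tuple[float, float] | None = None
    ci_i2: tuple[float, float] | None = None
    scale: str = "identity"


@dataclass
class MAPInterval:
    label: str
    point: float
    lo95: float
    hi95: float


@dataclass
class PooledSummary:
    unweighted_mean: float
    sd: float
    weighted_mean: float
    cv_percent: float


# ---------------------------------------------------------------------------
# Contrasts and rankings
# ---------------------------------------------------------------------------

def indirect_contrast(
    a: EffectEstimate,
    b: EffectEstimate,
    ni_margins: tuple[float, ...] = (),
    pooled_sd: float | None = None,
) -> ContrastResult:
    """Anchored indirect comparison of two placebo-controlled effects.

    ``p_superiority`` is the normal-theory probability that the observed
    direction of the contrast is the true one, Φ(|Δ|/SE).  For
    non-inferiority margins m > 0 (on the harm scale: ``a`` worse than
    ``b`` by m), ``p_noninferiority[m] = Φ((m − Δ)/SE)`` with
    Δ = etd_a − etd_b, i.e. the probability that ``a`` is not worse than
    ``b`` by more than m given lower (more negative) is better.
    """
    diff = a.etd - b.etd
    se = math.hypot(a.se, b.se)
    z = diff / se
    p = 2 * stats.norm.sf(abs(z))
    ni = {m: float(stats.norm.cdf((m - diff) / se)) for m in ni_margins}
    d = diff / pooled_sd if pooled_sd else None
    return ContrastResult(
        difference=diff,
        se_diff=se,
        ci95=(diff - 1.959963984540054 * se, diff + 1.959963984540054 * se),
        z=z,
        p_value=float(p),
        p_superiority=float(stats.norm.cdf(abs(z))),
        p_noninferiority=ni,
        cohens_d=d,
    )


def sucra(rank_probabilities: np.ndarray) -> np.ndarray:
    """Surface under the cumulative ranking curve, in percent.

    ``rank_probabilities[k, j]`` is treatment k's probability of holding
    rank j+1 (rank 1 = best).  SUCRA_k = 100·Σ_{j=1}^{K−1} cumP_k(j)/(K−1).
    A treatment certain to hold rank r scores 100·(K−r)/(K−1).
    """
    p = np.asarray(rank_probabilities, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError(f"rank matrix must be square, got {p.shape}")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("each treatment's rank probabilities must sum to 1")
    k = p.shape[0]
    if k == 1:
        return np.array([100.0])
    cum = np.cumsum(p, axis=1)[:, : k - 1]
    return 100.0 * cum.sum(axis=1) / (k - 1)


# ---------------------------------------------------------------------------
# Heterogeneity
# ---------------------------------------------------------------------------

def dl_heterogeneity(
    effects, variances, scale: str = "identity", ci_method: str = "q_profile"
) -> HeterogeneityEstimate:
    """DerSimonian-Laird between-study variance and I² with Q-profile CIs.

    Inverse-variance weights w_i = 1/v_i give Cochran's
    Q = Σ w_i (y_i − ȳ_w)², C = Σw − Σw²/Σw, τ² = max(0, (Q − df)/C) and
    I² = max(0, (Q − df)/Q).  The Q-profile CI inverts the generalized
    Q(τ²) statistic against χ²_df quantiles.
    """
    y = np.asarray(effects, dtype=float)
    v = np.asarray(variances, dtype=float)
    k = len(y)
    if k < 2:
        raise ValueError("need >= 2 studies")
    if np.any(v <= 0):
        raise ValueError("variances must be > 0")
    w = 1.0 / v
    ybar = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - ybar) ** 2))
    df = k - 1
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - df) / c)
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0

    ci_tau2 = ci_i2 = None
    if ci_method == "q_profile":
        ci_tau2 = _q_profile_ci(y, v, df)
        # translate through the "typical" within-study variance
        s2 = df * np.sum(w) / (np.sum(w) ** 2 - np.sum(w**2))
        ci_i2 = tuple(t / (t + s2) for t in ci_tau2)
    elif ci_method == "biggerstaff_tweedie":
        raise NotImplementedError(
            "Biggerstaff-Tweedie CIs are not implemented; use 'q_profile'")
    return HeterogeneityEstimate(tau2=tau2, i2_dl=i2, q=q, df=df,
                                 ci_tau2=ci_tau2, ci_i2=ci_i2, scale=scale)


def _gen_q(tau2: float, y, v) -> float:
    w = 1.0 / (v + tau2)
    ybar = np.sum(w * y) / np.sum(w)
    return float(np.sum(w * (y - ybar) ** 2))


def _q_profile_ci(y, v, df, level: float = 0.95) -> tuple[float, float]:
    lo_q = stats.chi2.ppf(1 - (1 - level) / 2, df)   # Q(τ²_lo) = upper χ² quantile
    hi_q = stats.chi2.ppf((1 - level) / 2, df)
    upper_cap = 100.0 * (np.max(v) + np.var(y))

    def bound(target):
        f = lambda t: _gen_q(t, y, v) - target
        if f(0.0) <= 0:                    # already below target at τ² = 0
            return 0.0
        if f(upper_cap) > 0:
            return upper_cap
        return float(optimize.brentq(f, 0.0, upper_cap, xtol=1e-12))

    return (bound(lo_q), bound(hi_q))


# ---------------------------------------------------------------------------
# MAP predictive intervals
# ---------------------------------------------------------------------------

def map_predictive_interval(
    pooled_logit: float, se_pooled: float, tau2: float,
    level: float = 0.95, label: str = "",
) -> MAPInterval:
    """Predictive interval for a future trial's proportion.

    On the logit scale: mean ± z·sqrt(se² + τ²), mapped back through the
    inverse logit; the point estimate is inverse-logit(mean).  Combines
    the pooled estimate's sampling uncertainty with genuine between-trial
    heterogeneity.
    """
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must lie in (0, 1), got {level}")
    if tau2 < 0:
        raise ValueError("tau2 must be >= 0")
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(se_pooled**2 + tau2)
    return MAPInterval(label=label,
                       point=_expit(pooled_logit),
                       lo95=_expit(pooled_logit - half),
                       hi95=_expit(pooled_logit + half))


# ---------------------------------------------------------------------------
# Pooled summaries and meta-regression
# ---------------------------------------------------------------------------

def pooled_summary(effects: list[EffectEstimate]) -> PooledSummary:
    """Unweighted mean ± SD, sample-size-weighted mean, and CV of effects."""
    if len(effects) < 2:
        raise ValueError("need >= 2 effects")
    y = np.array([e.etd for e in effects])
    n = np.array([e.n for e in effects], dtype=float)
    mean = float(y.mean())
    sd = float(y.std(ddof=1))
    wmean = float(np.sum(n * y) / np.sum(n))
    cv = 100.0 * sd / abs(mean) if mean != 0 else float("inf")
    return PooledSummary(unweighted_mean=mean, sd=sd, weighted_mean=wmean, cv_percent=cv)


def meta_regression_corr(modifier, effects) -> dict[str, float | tuple[float, float]]:
    """Pearson correlation between a trial-level modifier and effect sizes.

    Two-sided p from t = r·sqrt(n−2)/sqrt(1−r²); 95 % CI by Fisher-z.
    """
    x = np.asarray(modifier, dtype=float)
    y = np.asarray(effects, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need >= 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in modifier or effects")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        p = 0.0
        ci = (r, r)
    else:
        t = r * math.sqrt(n - 2) / math.sqrt(1 - r * r)
        p = float(2 * stats.t.sf(abs(t), n - 2))
        zr = math.atanh(r)
        half = 1.959963984540054 / math.sqrt(n - 3) if n > 3 else float("inf")
        ci = (math.tanh(zr - half), math.tanh(zr + half))
    return {"r": r, "p_value": p, "ci95": ci, "n": n}


# ---------------------------------------------------------------------------
# Transportability and confounding
# ---------------------------------------------------------------------------

def transport_weights(
    source_baselines: list[dict[str, float]],
    target_means: dict[str, float],
    target_cov: np.ndarray,
    arm_ids: list[str] | None = None,
) -> np.ndarray:
    """Mahalanobis-kernel weights re-calibrating records to a target population.

    w_i ∝ exp(−½ d_M(x_i, target)²) with d_M the Mahalanobis distance under
    the target covariance; weights are normalized to mean 1 within each arm
    (one arm assumed when ``arm_ids`` is None).
    """
    covs = sorted(target_means)
    x = np.array([[r[c] for c in covs] for r in source_baselines], dtype=float)
    mu = np.array([target_means[c] for c in covs])
    sigma = np.asarray(target_cov, dtype=float)
    try:
        sigma_inv = np.linalg.inv(sigma)
    except np.linalg.LinAlgError:
        bad = [covs[i] for i in range(len(covs)) if sigma[i, i] <= 0]
        raise ValueError(
            "singular target covariance"
            + (f" (degenerate covariates: {', '.join(bad)})" if bad else "")
        ) from None
    delta = x - mu
    d2 = np.einsum("ij,jk,ik->i", delta, sigma_inv, delta)
    w = np.exp(-0.5 * (d2 - d2.min()))   # shift for numerical range only
    groups = np.zeros(len(x), dtype=int) if arm_ids is None else (
        np.unique(arm_ids, return_inverse=True)[1])
    for g in np.unique(groups):
        mask = groups == g
        w[mask] = w[mask] / w[mask].mean()
    return w


def e_value(rr: float) -> float:
    """Minimum confounder strength (risk-ratio scale) to explain away RR.

    E = RR + sqrt(RR·(RR − 1)); protective ratios (RR < 1) are inverted
    first, so e_value(x) == e_value(1/x).
    """
    if rr <= 0:
        raise ValueError(f"risk ratio must be > 0, got {rr}")
    if rr < 1:
        rr = 1.0 / rr
    return rr + math.sqrt(rr * (rr - 1.0))
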