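"""Trial-design operating characteristics.

Closed-form normal-approximation power for two-arm superiority,
non-inferiority and equivalence designs on a continuous endpoint;
Lan-DeMets error-spending group-sequential boundaries (O'Brien-Fleming and
Pocock types) computed by numerical integration of the canonical joint
distribution of sequential z-statistics; expected sample size under early
stopping; conditional-power sample-size re-estimation with an inflation
cap; exponential retention/completion curves; and replicate-based virtual
head-to-head simulation with empirical power and type-I error.

The two-arm difference of means has SE = sd·sqrt(2/n) per arm; covariate
adjustment (ANCOVA) is represented, when requested, by deflating sd by
sqrt(1 − ρ²) for a baseline correlation ρ.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "DesignSpec",
    "OperatingCharacteristics",
    "GSDBoundary",
    "se_of_difference",
    "sd_from_se",
    "power_two_arm",
    "power_noninferiority",
    "power_equivalence",
    "gsd_boundaries",
    "expected_sample_size",
    "sample_size_reestimation",
    "completion_curve",
    "simulate_h2h",
]

_Z = stats.norm


@dataclass
class DesignSpec:
    design: str = "superiority"      # superiority | noninferiority | equivalence
    effect: float = 0.0              # pp, signed; magnitude is what powers the test
    sd: float = 1.0                  # pp, common within-arm SD
    n_per_arm: int = 2
    alpha: float = 0.05              # two-sided
    margin: float | None = None      # pp, NI/equivalence
    ancova_rho: float = 0.0          # baseline correlation absorbed by ANCOVA

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_per_arm < 2:
            raise ValueError("n_per_arm must be >= 2")
        if not self.sd > 0:
            raise ValueError("sd must be > 0")

    @property
    def effective_sd(self) -> float:
        return self.sd * math.sqrt(1.0 - self.ancova_rho**2)


@dataclass
class OperatingCharacteristics:
    power: float
    type1: float
    se_effect: float
    expected_n: float | None = None
    stop_probabilities: list[float] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)


@dataclass
class GSDBoundary:
    looks: list[dict[str, float]]    # info_fraction, z_boundary, alpha_spent
    alpha: float
    spending: str

    @property
    def z_boundaries(self) -> list[float]:
        return [lk["z_boundary"] for lk in self.looks]


# ---------------------------------------------------------------------------
# Closed-form power
# ---------------------------------------------------------------------------

def se_of_difference(sd: float, n_per_arm: int) -> float:
    """SE of a two-arm difference in means: sd·sqrt(2/n)."""
    if not sd > 0 or n_per_arm < 1:
        raise ValueError("sd must be > 0 and n_per_arm >= 1")
    return sd * math.sqrt(2.0 / n_per_arm)


def sd_from_se(se: float, n_per_arm: int) -> float:
    """Back-solve the common within-arm SD from a reported difference SE."""
    return se / math.sqrt(2.0 / n_per_arm)


def power_two_arm(spec: DesignSpec) -> OperatingCharacteristics:
    """Normal-approximation power for a two-arm superiority comparison.

    1 − β = Φ(|Δ|/SE − z_{1−α/2}) (the opposite-tail term is negligible at
    any realistic power and is included for exactness).  A zero effect
    returns power α/2 one-sided with a null-design warning note.
    """
    se = se_of_difference(spec.effective_sd, spec.n_per_arm)
    z_a = _Z.ppf(1 - spec.alpha / 2)
    shift = abs(spec.effect) / se
    power = float(_Z.cdf(shift - z_a) + _Z.cdf(-shift - z_a))
    notes = []
    if spec.effect == 0:
        notes.append("null design: effect = 0, 'power' is the one-sided type-I rate")
        warnings.warn(notes[0], stacklevel=2)
    return OperatingCharacteristics(power=power, type1=spec.alpha,
                                    se_effect=se, notes=notes)


def power_noninferiority(spec: DesignSpec) -> OperatingCharacteristics:
    """Power to show non-inferiority at margin m (shift-by-margin normal test).

    With true advantage δ = |effect| toward benefit (0 under an equal-arms
    assumption, negative when truly worse), the one-sided level α/2 test of
    H0: difference ≤ −m has power Φ((m + δ)/SE − z_{1−α/2}).
    """
    if spec.margin is None or spec.margin <= 0:
        raise ValueError("non-inferiority requires margin > 0")
    se = se_of_difference(spec.effective_sd, spec.n_per_arm)
    z_a = _Z.ppf(1 - spec.alpha / 2)
    power = float(_Z.cdf((spec.margin + spec.effect) / se - z_a))
    return OperatingCharacteristics(power=power, type1=spec.alpha / 2, se_effect=se)


def power_equivalence(spec: DesignSpec) -> OperatingCharacteristics:
    """TOST equivalence power at symmetric margins ±m."""
    if spec.margin is None or spec.margin <= 0:
        raise ValueError("equivalence requires margin > 0")
    se = se_of_difference(spec.effective_sd, spec.n_per_arm)
    z_a = _Z.ppf(1 - spec.alpha / 2)
    m, d = spec.margin, spec.effect
    power = max(0.0, float(_Z.cdf((m - d) / se - z_a) + _Z.cdf((m + d) / se - z_a) - 1.0))
    return OperatingCharacteristics(power=power, type1=spec.alpha / 2, se_effect=se)


# ---------------------------------------------------------------------------
# Group-sequential boundaries
# ---------------------------------------------------------------------------

def _spending(t: float, alpha_one: float, kind: str) -> float:
    """Cumulative one-sided error spent at information fraction t."""
    t = min(max(t, 1e-12), 1.0)
    if kind == "obf":
        # Lan-DeMets O'Brien-Fleming-type spending
        return 2.0 * (1.0 - _Z.cdf(_Z.ppf(1 - alpha_one / 2) / math.sqrt(t)))
    if kind == "pocock":
        return alpha_one * math.log(1.0 + (math.e - 1.0) * t)
    raise ValueError(f"unknown spending function {kind!r}")


def gsd_boundaries(
    alpha: float = 0.05,
    info_fractions: tuple[float, ...] = (0.5, 1.0),
    spending: str = "obf",
    grid_points: int = 4001,
    z_span: float = 8.0,
) -> GSDBoundary:
    """Error-spending efficacy boundaries for a group-sequential design.

    Two-sided ``alpha`` is handled as symmetric one-sided spending of
    α/2.  Sequential z-statistics follow the canonical multivariate normal
    with Cov(Z_i, Z_j) = sqrt(t_i/t_j); boundaries are solved look by look
    so the incremental crossing probability matches the spending-function
    increment, propagating the continuation density by numerical
    (trapezoid) convolution on a z-grid.
    """
    t = list(info_fractions)
    if any(b <= a for a, b in zip(t, t[1:])) or t[-1] > 1.0 or t[0] <= 0:
        raise ValueError("info fractions must be strictly increasing in (0, 1]")
    if abs(t[-1] - 1.0) > 1e-12:
        raise ValueError("final information fraction must be 1.0")
    alpha_one = alpha / 2.0

    z = np.linspace(-z_span, z_span, grid_points)
    dz = z[1] - z[0]
    looks = []
    # density of the current look's z-statistic restricted to "not yet stopped"
    dens = None
    cum_spent_prev = 0.0
    for k, tk in enumerate(t):
        cum_spent = _spending(tk, alpha_one, spending) if k < len(t) - 1 else alpha_one
        inc = max(cum_spent - cum_spent_prev, 0.0)
        if k == 0:
            dens = stats.norm.pdf(z)
        else:
            # Z_k | Z_{k-1}: increment independence on the sqrt-information scale
            r = math.sqrt(t[k - 1] / tk)
            s = math.sqrt(1.0 - r * r)
            # transition kernel: column j -> density at z_i
            kernel = stats.norm.pdf((z[:, None] - r * z[None, :]) / s) / s
            dens = kernel @ dens * dz

        def exceed(b):
            # one-sided mass above b under the continuation density, with the
            # partial cell at the cut handled by linear interpolation
            idx = int(np.searchsorted(z, b))
            if idx >= len(z):
                return 0.0
            full = float(np.trapezoid(dens[idx:], z[idx:]))
            if idx == 0:
                return full
            fb = float(np.interp(b, z, dens))
            partial = 0.5 * (fb + dens[idx]) * (z[idx] - b)
            return full + partial

        if inc <= 0:
            zb = z_span
        else:
            zb = float(optimize.brentq(lambda b: exceed(b) - inc, 0.0, z_span,
                                       xtol=1e-10))
        looks.append({"info_fraction": tk, "z_boundary": zb, "alpha_spent": cum_spent})
        # restrict the density to the continuation region |Z| < boundary
        dens = np.where(np.abs(z) < zb, dens, 0.0)
        cum_spent_prev = cum_spent
    return GSDBoundary(looks=looks, alpha=alpha, spending=spending)


def expected_sample_size(
    boundary_or_n: GSDBoundary | list[float],
    stop_probs: list[float],
    n_per_look: list[float] | None = None,
) -> float:
    """E[N] = Σ n_k · P(stop at look k); probabilities must sum to 1."""
    n_looks = n_per_look if n_per_look is not None else boundary_or_n
    if not isinstance(n_looks, (list, tuple, np.ndarray)):
        raise ValueError("per-look sample sizes required")
    p = np.asarray(stop_probs, dtype=float)
    if np.any(p < 0) or np.any(p > 1) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("stop probabilities must lie in [0, 1] and sum to 1")
    n = np.asarray(n_looks, dtype=float)
    if len(n) != len(p):
        raise ValueError("length mismatch between looks and probabilities")
    return float(np.sum(n * p))


def sample_size_reestimation(
    interim_effect: float,
    interim_se: float,
    target_power: float,
    max_inflation: float = 2.0,
    planned_n_per_arm: int = 100,
    alpha: float = 0.05,
) -> int:
    """Conditional-power sample-size re-estimation with an inflation cap.

    ``interim_se`` is the SE of the difference at the *planned* size, so the
    implied within-arm SD is interim_se·sqrt(n_planned/2).  The returned n
    solves the normal power equation at the interim effect estimate,
    floored at the planned size and capped at ``max_inflation`` × planned.
    """
    if interim_se <= 0:
        raise ValueError("interim_se must be > 0")
    if max_inflation < 1:
        raise ValueError("max_inflation must be >= 1")
    sd = sd_from_se(interim_se, planned_n_per_arm)
    z_a = _Z.ppf(1 - alpha / 2)
    z_b = _Z.ppf(target_power)
    eff = abs(interim_effect)
    if eff == 0:
        n_needed = float("inf")
    else:
        n_needed = 2.0 * (sd * (z_a + z_b) / eff) ** 2
    cap = max_inflation * planned_n_per_arm
    return int(min(max(math.ceil(n_needed), planned_n_per_arm), math.floor(cap)))


# ---------------------------------------------------------------------------
# Retention
# ---------------------------------------------------------------------------

def completion_curve(
    annual_dropout: float,
    extra_hazards: dict[str, float] | None = None,
    horizon: float = 68.0,
    weeks: np.ndarray | None = None,
) -> dict[float, float]:
    """Exponential retention curve from an annual attrition proportion.

    Weekly hazard −ln(1 − annual)/52 anchors retention(52) = 1 − annual
    exactly; ``extra_hazards`` adds further annual-proportion components
    (early termination, protocol deviation) on the hazard scale.
    """
    rates = {"attrition": annual_dropout, **(extra_hazards or {})}
    lam = 0.0
    for name, r in rates.items():
        if not (0.0 <= r < 1.0):
            raise ValueError(f"annual proportion {name!r} = {r} outside [0, 1)")
        lam += -math.log1p(-r) / 52.0
    if weeks is None:
        weeks = np.arange(0.0, horizon + 1e-9, 1.0)
    return {float(w): float(math.exp(-lam * w)) for w in np.asarray(weeks, dtype=float)}


# ---------------------------------------------------------------------------
# Virtual head-to-head simulation
# ---------------------------------------------------------------------------

def simulate_h2h(
    arm_specs: list[dict],
    n_replicates: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
    ni_margin: float | None = None,
) -> dict:
    """Replicate-based two-arm simulation with empirical operating characteristics.

    Each arm spec carries ``mean`` (pp), ``sd`` (pp), ``n`` and optional
    ``dropout`` (proportion lost completely at random).  Per replicate the
    difference in means, Welch z-test p-value, and 95 % CI are recorded;
    the rejection rate comes with its binomial Monte-Carlo SE.  With
    ``ni_margin`` the test is one-sided non-inferiority at level α/2
    (arm 0 not worse than arm 1 by more than the margin, lower = better).
    """
    if len(arm_specs) != 2:
        raise ValueError("simulate_h2h compares exactly two arms")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    samples = []
    for spec in arm_specs:
        n = int(spec["n"])
        keep = n
        if spec.get("dropout"):
            keep = max(2, int(round(n * (1.0 - spec["dropout"]))))
        x = rng.normal(spec["mean"], spec["sd"], size=(n_replicates, keep))
        samples.append(x)
    m0, m1 = samples[0].mean(axis=1), samples[1].mean(axis=1)
    v0 = samples[0].var(axis=1, ddof=1) / samples[0].shape[1]
    v1 = samples[1].var(axis=1, ddof=1) / samples[1].shape[1]
    diff = m0 - m1
    se = np.sqrt(v0 + v1)
    z_a = _Z.ppf(1 - alpha / 2)
    ci_lo, ci_hi = diff - z_a * se, diff + z_a * se
    if ni_margin is not None:
        # H0: diff >= margin (arm 0 worse); reject when z < -z_{1-alpha/2}
        zstat = (diff - ni_margin) / se
        reject = zstat < -z_a
    else:
        zstat = diff / se
        reject = np.abs(zstat) > z_a
    rate = float(reject.mean())
    return {
        "differences": diff,
        "se": se,
        "ci_lo": ci_lo,
        "ci_hi": ci_hi,
        "rejection_rate": rate,
        "mc_se": math.sqrt(max(rate * (1 - rate), 1e-12) / n_replicates),
        "n_replicates": n_replicates,
    }
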