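"""Arm-level aggregate trial summaries: data model, validation, I/O, fixtures.

Published obesity/diabetes pharmacotherapy trials report their results as
arm-level aggregates — per-arm sample sizes, baseline covariate means/SDs
(age, BMI, weight, HbA1c), visit-wise mean weight change with standard
errors, responder proportions at weight-loss thresholds, adverse-event and
discontinuation proportions, and the randomized dose.  Everything downstream
(synthetic patient reconstruction, dose-response fitting, evidence
synthesis, trial simulation) consumes these tables, so this module owns the
single validated in-memory representation and its CSV/JSON round-trip.

Conventions
-----------
* Proportions live in ``[0, 1]`` internally; percent appears only in
  reports.
* Weight change is stored signed: losses are negative percentage points.
* Responder thresholds are percentage points of weight loss; the reported
  proportion must be non-increasing as the threshold rises.
"""

from __future__ import annotations

import csv
import io
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SchemaError",
    "ValidationError",
    "ConfigError",
    "VisitSummary",
    "ArmSummary",
    "AggregateTrialTable",
    "FixtureConfig",
    "read_table",
    "write_table",
    "generate_fixture",
    "se_from_ci",
]

#: Covariates every baseline block may carry, with display units.
BASELINE_COVARIATES = ("age", "bmi", "weight", "hba1c")

ROUTES = ("sc_weekly", "oral_daily", "none")
ENDPOINTS = ("weight_pct", "hba1c_pp")
POPULATIONS = ("obesity", "t2d", "healthy")


class SchemaError(ValueError):
    """A file does not conform to the documented column/key schema."""


class ValidationError(ValueError):
    """A table violates a domain invariant (named in the message)."""


class ConfigError(ValueError):
    """Invalid fixture-generator configuration."""


def se_from_ci(lo: float, hi: float) -> float:
    """Standard error reconstructed from a 95 % confidence interval.

    ``(hi - lo) / 3.92`` — the normal-theory width of a two-sided 95 % CI.
    Used at read time when a source reports CIs but no SE; callers should
    flag the provenance of the resulting field.
    """
    if hi < lo:
        raise ValidationError(f"CI upper bound {hi} below lower bound {lo}")
    return (hi - lo) / 3.92


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VisitSummary:
    """One scheduled visit's reported outcome summary for an arm."""

    week: float
    mean_change: float
    se: float
    endpoint: str = "weight_pct"

    def __post_init__(self) -> None:
        if self.week < 0:
            raise ValidationError(f"visit week {self.week} < 0")
        if not self.se > 0:
            raise ValidationError(f"visit SE must be > 0, got {self.se}")
        if self.endpoint not in ENDPOINTS:
            raise ValidationError(f"unknown endpoint {self.endpoint!r}")


@dataclass
class ArmSummary:
    """Published aggregate description of a single randomized arm."""

    trial_id: str
    arm_id: str
    treatment: str
    dose: float
    route: str
    n: int
    duration: float
    baseline_means: dict[str, float] = field(default_factory=dict)
    baseline_sds: dict[str, float] = field(default_factory=dict)
    baseline_corr: np.ndarray | None = None
    visits: list[VisitSummary] = field(default_factory=list)
    responder_rates: dict[float, float] = field(default_factory=dict)
    ae_rates: dict[str, float] = field(default_factory=dict)
    discontinuation_rate: float = 0.0

    @property
    def is_placebo(self) -> bool:
        return self.dose == 0

    def covariates(self) -> list[str]:
        return sorted(self.baseline_means)

    def validate(self) -> None:
        a = self.arm_id
        if self.n < 1:
            raise ValidationError(f"arm {a}: n must be >= 1, got {self.n}")
        if self.dose < 0:
            raise ValidationError(f"arm {a}: dose {self.dose} < 0")
        if self.route not in ROUTES:
            raise ValidationError(f"arm {a}: unknown route {self.route!r}")
        for name, p in [("discontinuation_rate", self.discontinuation_rate),
                        *[(f"ae_rate[{k}]", v) for k, v in self.ae_rates.items()],
                        *[(f"responder_rate[{k}]", v) for k, v in self.responder_rates.items()]]:
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"arm {a}: {name} = {p} outside [0, 1]")
        for cov in self.baseline_means:
            sd = self.baseline_sds.get(cov)
            if sd is None:
                raise ValidationError(f"arm {a}: covariate {cov!r} has mean but no SD")
            if sd < 0:
                raise ValidationError(f"arm {a}: SD of {cov!r} is negative")
        # Responder ladder: proportion cannot rise with a stricter threshold.
        thresholds = sorted(self.responder_rates)
        for lo, hi in zip(thresholds, thresholds[1:]):
            if self.responder_rates[hi] > self.responder_rates[lo] + 1e-12:
                raise ValidationError(
                    f"arm {a}: responder rate at >={hi} pp ({self.responder_rates[hi]}) "
                    f"exceeds rate at >={lo} pp ({self.responder_rates[lo]})"
                )
        weeks = [v.week for v in self.visits]
        if any(w2 <= w1 for w1, w2 in zip(weeks, weeks[1:])):
            raise ValidationError(f"arm {a}: visit weeks not strictly increasing: {weeks}")
        if self.baseline_corr is not None:
            c = np.asarray(self.baseline_corr, dtype=float)
            d = len(self.covariates())
            if c.shape != (d, d):
                raise ValidationError(f"arm {a}: correlation matrix shape {c.shape} != ({d}, {d})")
            if not np.allclose(c, c.T, atol=1e-8):
                raise ValidationError(f"arm {a}: correlation matrix not symmetric")
            if not np.allclose(np.diag(c), 1.0, atol=1e-8):
                raise ValidationError(f"arm {a}: correlation diagonal not 1")
            if np.linalg.eigvalsh(c).min() < -1e-8:
                raise ValidationError(f"arm {a}: correlation matrix not positive semidefinite")


@dataclass
class AggregateTrialTable:
    """A collection of arms across one or more trials, plus study metadata."""

    arms: list[ArmSummary]
    meta: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if not self.arms:
            raise ValidationError("table has no arms")
        ids = [(a.trial_id, a.arm_id) for a in self.arms]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate (trial_id, arm_id) pairs")
        pop = self.meta.get("population")
        if pop is not None and pop not in POPULATIONS:
            raise ValidationError(f"unknown population {pop!r}")
        for arm in self.arms:
            arm.validate()

    def trial_ids(self) -> list[str]:
        seen: list[str] = []
        for a in self.arms:
            if a.trial_id not in seen:
                seen.append(a.trial_id)
        return seen

    def arms_of(self, trial_id: str) -> list[ArmSummary]:
        return [a for a in self.arms if a.trial_id == trial_id]


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_MANDATORY_CSV = [
    "trial_id", "arm_id", "treatment", "dose", "route", "n", "duration",
    "week", "mean_change", "se", "endpoint",
]
_ARM_JSON_COLS = [
    "baseline_means", "baseline_sds", "baseline_corr",
    "responder_rates", "ae_rates",
]


def _arm_to_dict(arm: ArmSummary) -> dict:
    d = {
        "trial_id": arm.trial_id,
        "arm_id": arm.arm_id,
        "treatment": arm.treatment,
        "dose": arm.dose,
        "route": arm.route,
        "n": arm.n,
        "duration": arm.duration,
        "baseline_means": arm.baseline_means,
        "baseline_sds": arm.baseline_sds,
        "responder_rates": {str(k): v for k, v in arm.responder_rates.items()},
        "ae_rates": arm.ae_rates,
        "discontinuation_rate": arm.discontinuation_rate,
        "visits": [
            {"week": v.week, "mean_change": v.mean_change, "se": v.se,
             "endpoint": v.endpoint}
            for v in arm.visits
        ],
    }
    if arm.baseline_corr is not None:
        d["baseline_corr"] = np.asarray(arm.baseline_corr).tolist()
    return d


def _arm_from_dict(d: dict) -> ArmSummary:
    corr = d.get("baseline_corr")
    return ArmSummary(
        trial_id=str(d["trial_id"]),
        arm_id=str(d["arm_id"]),
        treatment=str(d["treatment"]),
        dose=float(d["dose"]),
        route=str(d["route"]),
        n=int(d["n"]),
        duration=float(d["duration"]),
        baseline_means={k: float(v) for k, v in d.get("baseline_means", {}).items()},
        baseline_sds={k: float(v) for k, v in d.get("baseline_sds", {}).items()},
        baseline_corr=None if corr is None else np.asarray(corr, dtype=float),
        visits=[VisitSummary(week=float(v["week"]), mean_change=float(v["mean_change"]),
                             se=float(v["se"]), endpoint=v.get("endpoint", "weight_pct"))
                for v in d.get("visits", [])],
        responder_rates={float(k): float(v) for k, v in d.get("responder_rates", {}).items()},
        ae_rates={k: float(v) for k, v in d.get("ae_rates", {}).items()},
        discontinuation_rate=float(d.get("discontinuation_rate", 0.0)),
    )


def write_table(table: AggregateTrialTable, path, format: str = "csv") -> None:
    """Serialize a validated table; ``read_table`` inverts it field-for-field.

    CSV is long form: one row per arm-visit, arm-level mappings carried as
    JSON cells (repeated on each of the arm's rows).  JSON is nested.
    """
    table.validate()
    if format == "json":
        payload = {"meta": table.meta, "arms": [_arm_to_dict(a) for a in table.arms]}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)
        return
    if format != "csv":
        raise SchemaError(f"unknown format {format!r}")

    cols = _MANDATORY_CSV + _ARM_JSON_COLS + ["discontinuation_rate",
                                              "meta_phase", "meta_population", "meta_design"]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=cols)
        w.writeheader()
        for arm in table.arms:
            d = _arm_to_dict(arm)
            base = {
                **{k: d[k] for k in ("trial_id", "arm_id", "treatment", "dose",
                                     "route", "n", "duration", "discontinuation_rate")},
                "baseline_means": json.dumps(d["baseline_means"]),
                "baseline_sds": json.dumps(d["baseline_sds"]),
                "baseline_corr": json.dumps(d.get("baseline_corr")) if "baseline_corr" in d else "",
                "responder_rates": json.dumps(d["responder_rates"]),
                "ae_rates": json.dumps(d["ae_rates"]),
                "meta_phase": table.meta.get("phase", ""),
                "meta_population": table.meta.get("population", ""),
                "meta_design": table.meta.get("design", ""),
            }
            visits = arm.visits or [None]
            for v in visits:
                row = dict(base)
                if v is None:
                    row.update(week="", mean_change="", se="", endpoint="")
                else:
                    row.update(week=v.week, mean_change=v.mean_change,
                               se=v.se, endpoint=v.endpoint)
                w.writerow(row)


def read_table(path, format: str = "csv") -> AggregateTrialTable:
    """Parse and fully validate an aggregate table from disk."""
    if format == "json":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        if "arms" not in payload:
            raise SchemaError("missing mandatory key 'arms'")
        table = AggregateTrialTable(
            arms=[_arm_from_dict(d) for d in payload["arms"]],
            meta={k: str(v) for k, v in payload.get("meta", {}).items()},
        )
        table.validate()
        return table
    if format != "csv":
        raise SchemaError(f"unknown format {format!r}")

    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError("empty file: header row required")
        missing = [c for c in _MANDATORY_CSV if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
        rows = list(reader)

    arms: dict[tuple[str, str], dict] = {}
    meta: dict[str, str] = {}
    for row in rows:
        key = (row["trial_id"], row["arm_id"])
        if key not in arms:
            corr_cell = row.get("baseline_corr", "")
            d = {
                "trial_id": row["trial_id"],
                "arm_id": row["arm_id"],
                "treatment": row["treatment"],
                "dose": row["dose"],
                "route": row["route"],
                "n": row["n"],
                "duration": row["duration"],
                "baseline_means": json.loads(row.get("baseline_means") or "{}"),
                "baseline_sds": json.loads(row.get("baseline_sds") or "{}"),
                "responder_rates": json.loads(row.get("responder_rates") or "{}"),
                "ae_rates": json.loads(row.get("ae_rates") or "{}"),
                "discontinuation_rate": row.get("discontinuation_rate") or 0.0,
                "visits": [],
            }
            corr = json.loads(corr_cell) if corr_cell else None
            if corr is not None:
                d["baseline_corr"] = corr
            arms[key] = d
        if row.get("week", "") != "":
            arms[key]["visits"].append(
                {"week": row["week"], "mean_change": row["mean_change"],
                 "se": row["se"], "endpoint": row.get("endpoint") or "weight_pct"}
            )
        for mk in ("phase", "population", "design"):
            v = row.get(f"meta_{mk}", "")
            if v:
                meta[mk] = v

    table = AggregateTrialTable(arms=[_arm_from_dict(d) for d in arms.values()], meta=meta)
    table.validate()
    return table


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureConfig:
    """Controls the synthetic aggregate-table generator.

    Defaults emulate the structure of a multi-trial amylin-pathway
    development program: a handful of trials, placebo plus ascending active
    doses, arm sizes spanning early-phase (tens) to confirmatory
    (thousands), 3–12 scheduled visits, monotone responder ladders at the
    5/10/15 pp thresholds, and GI adverse-event and discontinuation rates
    that rise with dose.
    """

    n_trials: int = 2
    arms_per_trial: int = 3
    n_range: tuple[int, int] = (10, 2500)
    visit_count: int = 6
    seed: int = 0
    population: str = "obesity"
    duration: float = 48.0

    def validate(self) -> None:
        if self.n_trials < 1 or self.arms_per_trial < 1:
            raise ConfigError("n_trials and arms_per_trial must be positive")
        if self.visit_count < 3 or self.visit_count > 12:
            raise ConfigError("visit_count must be in [3, 12]")
        lo, hi = self.n_range
        if lo < 5 or hi < lo:
            raise ConfigError(f"invalid n_range {self.n_range}")


# Generative anchors for the fixture, loosely matching published obesity
# pharmacology trials: weight-loss efficacy saturating in dose, GI-AE and
# discontinuation odds rising in dose from a placebo background.
_FIX_EMAX = 22.0        # pp maximal placebo-adjusted loss
_FIX_ED50 = 3.0         # mg
_FIX_PLACEBO_DRIFT = -2.0  # pp loss on placebo at end of study
_FIX_K = 0.06           # per-week approach to plateau


def _fixture_corr(rng: np.random.Generator, d: int) -> np.ndarray:
    """Random well-conditioned correlation matrix (unit diagonal, PSD)."""
    a = rng.normal(size=(d, d + 2))
    cov = a @ a.T + d * np.eye(d)
    s = np.sqrt(np.diag(cov))
    return cov / np.outer(s, s)


def generate_fixture(config: FixtureConfig) -> AggregateTrialTable:
    """Deterministically generate a valid aggregate table for testing.

    Responder rates are emitted as exact event-count fractions (k/n), the
    way published tables arise, so that integer responder assignment can
    reproduce them exactly downstream.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    t2d = config.population == "t2d"
    arms: list[ArmSummary] = []
    doses = [0.0] + sorted(rng.uniform(1.0, 60.0, size=config.arms_per_trial - 1).tolist())
    for t in range(config.n_trials):
        trial_id = f"TRIAL-{t + 1}"
        for j in range(config.arms_per_trial):
            dose = doses[j] if config.arms_per_trial > 1 else 0.0
            n = int(rng.integers(config.n_range[0], config.n_range[1] + 1))
            means = {
                "age": float(rng.uniform(40, 58)),
                "bmi": float(rng.uniform(31, 38)),
                "weight": float(rng.uniform(95, 110)),
                "hba1c": float(rng.uniform(7.8, 8.4)) if t2d else float(rng.uniform(5.3, 5.7)),
            }
            sds = {
                "age": float(rng.uniform(9, 13)),
                "bmi": float(rng.uniform(5, 7)),
                "weight": float(rng.uniform(15, 22)),
                "hba1c": float(rng.uniform(0.3, 0.9)),
            }
            corr = _fixture_corr(rng, 4)

            # Saturating mean-loss trajectory with mild reporting noise.
            final = _FIX_PLACEBO_DRIFT + -_FIX_EMAX * dose / (_FIX_ED50 + dose)
            weeks = np.linspace(4, config.duration, config.visit_count)
            sd_out = rng.uniform(6.0, 10.0)
            visits = [
                VisitSummary(
                    week=float(w),
                    mean_change=float(final * (1 - math.exp(-_FIX_K * w))
                                      + rng.normal(0, 0.1)),
                    se=float(sd_out / math.sqrt(n)),
                )
                for w in weeks
            ]

            # Monotone responder ladder from the implied final loss; counts
            # drawn then expressed as exact fractions of n.
            final_mean = visits[-1].mean_change
            rates = {}
            for thr in (5.0, 10.0, 15.0):
                p = float(np.clip(0.5 + (-final_mean - thr) / 12.0, 0.02, 0.98))
                rates[thr] = p
            ladder = np.minimum.accumulate([rates[5.0], rates[10.0], rates[15.0]])
            counts = np.round(ladder * n).astype(int)
            counts = np.minimum.accumulate(counts)
            responder_rates = {thr: int(c) / n for thr, c in zip((5.0, 10.0, 15.0), counts)}

            gi = float(np.clip(0.25 + 0.55 * dose / (8.0 + dose) + rng.normal(0, 0.02), 0.01, 0.97))
            disc = float(np.clip(0.05 + 0.20 * dose / (20.0 + dose) + rng.normal(0, 0.01), 0.0, 0.5))
            # store as achievable count fractions too
            gi = round(gi * n) / n
            disc = round(disc * n) / n

            arms.append(ArmSummary(
                trial_id=trial_id,
                arm_id=f"{trial_id}-A{j + 1}",
                treatment="placebo" if dose == 0 else "active",
                dose=float(dose),
                route="none" if dose == 0 else "sc_weekly",
                n=n,
                duration=config.duration,
                baseline_means=means,
                baseline_sds=sds,
                baseline_corr=corr,
                visits=visits,
                responder_rates=responder_rates,
                ae_rates={"gi": gi},
                discontinuation_rate=disc,
            ))
    table = AggregateTrialTable(arms=arms, meta={"phase": "fixture",
                                                 "population": config.population,
                                                 "design": "synthetic fixture"})
    table.validate()
    return table


def tables_equal(a: AggregateTrialTable, b: AggregateTrialTable, tol: float = 1e-9) -> bool:
    """Field-level equality of two tables up to numeric tolerance."""
    if a.meta != b.meta or len(a.arms) != len(b.arms):
        return False
    for x, y in zip(a.arms, b.arms):
        dx, dy = _arm_to_dict(x), _arm_to_dict(y)
        if not _dict_close(dx, dy, tol):
            return False
    return True


def _dict_close(x, y, tol) -> bool:
    if isinstance(x, dict) and isinstance(y, dict):
        return x.keys() == y.keys() and all(_dict_close(x[k], y[k], tol) for k in x)
    if isinstance(x, (list, tuple)) and isinstance(y, (list, tuple)):
        return len(x) == len(y) and all(_dict_close(a, b, tol) for a, b in zip(x, y))
    if isinstance(x, float) or isinstance(y, float):
        return math.isclose(float(x), float(y), rel_tol=0.0, abs_tol=tol)
    return x == y
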