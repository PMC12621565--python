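"""Evidence synthesis: contrasts, SUCRA, heterogeneity, MAP, pooling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synthtte.synthesis import (
    EffectEstimate,
    dl_heterogeneity,
    e_value,
    indirect_contrast,
    map_predictive_interval,
    meta_regression_corr,
    pooled_summary,
    sucra,
    transport_weights,
)

CS_OB = EffectEstimate("cagrisema_obesity", -17.3, 0.33, n=2108)
SEMA = EffectEstimate("semaglutide", -11.9, 0.86, n=302)
CS_T2D = EffectEstimate("cagrisema_t2d", -10.4, 0.50, n=904)


# ---------------------------------------------------------------------------
# Contrasts
# ---------------------------------------------------------------------------

def test_contrast_published_rows():
    r = indirect_contrast(CS_OB, SEMA)
    assert r.difference == pytest.approx(-5.4, abs=1e-9)
    assert r.ci95[0] == pytest.approx(-7.2, abs=0.05)
    assert r.ci95[1] == pytest.approx(-3.6, abs=0.05)
    r2 = indirect_contrast(CS_OB, CS_T2D)
    assert r2.difference == pytest.approx(-6.9, abs=1e-9)


def test_contrast_self_comparison():
    r = indirect_contrast(CS_OB, CS_OB)
    assert r.difference == 0.0
    assert r.p_superiority == pytest.approx(0.5)
    assert r.p_value == pytest.approx(1.0)


def test_contrast_noninferiority_and_d():
    r = indirect_contrast(CS_OB, SEMA, ni_margins=(2.0,), pooled_sd=9.0)
    assert r.p_noninferiority[2.0] > 0.999  # far better than the margin
    assert r.cohens_d == pytest.approx(-5.4 / 9.0)


def test_contrast_invalid_se():
    with pytest.raises(ValueError):
        EffectEstimate("bad", -5.0, 0.0)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(e1=st.floats(-25, 0), e2=st.floats(-25, 0),
       s1=st.floats(0.1, 3), s2=st.floats(0.1, 3))
def test_contrast_antisymmetric(e1, e2, s1, s2):
    a = EffectEstimate("a", e1, s1)
    b = EffectEstimate("b", e2, s2)
    ab, ba = indirect_contrast(a, b), indirect_contrast(b, a)
    assert ab.difference == pytest.approx(-ba.difference)
    assert ab.se_diff == pytest.approx(ba.se_diff)
    assert abs(ab.z) == pytest.approx(abs(ba.z))


# ---------------------------------------------------------------------------
# SUCRA
# ---------------------------------------------------------------------------

def test_sucra_degenerate_ladder():
    p = np.eye(10)
    scores = sucra(p)
    assert scores[0] == pytest.approx(100.0)
    assert scores[1] == pytest.approx(88.888888, rel=1e-6)
    assert scores[-1] == pytest.approx(0.0)
    assert np.allclose(np.diff(scores), -100 / 9)


def test_sucra_uniform_is_half():
    k = 7
    scores = sucra(np.full((k, k), 1 / k))
    assert np.allclose(scores, 50.0)


def test_sucra_invalid_rows():
    p = np.eye(4)
    p[0, 0] = 0.8
    with pytest.raises(ValueError, match="sum to 1"):
        sucra(p)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(2, 8), st.integers(0, 1000))
def test_sucra_mean_is_fifty(k, seed):
    """Mean SUCRA across treatments is 50 % for any rank-probability matrix
    arising from a distribution over rankings (empirical rank counts)."""
    rng = np.random.default_rng(seed)
    counts = np.zeros((k, k))
    for _ in range(50):
        order = np.argsort(rng.normal(size=k))  # a random full ranking
        counts[order, np.arange(k)] += 1
    p = counts / 50
    assert sucra(p).mean() == pytest.approx(50.0, abs=1e-9)


# ---------------------------------------------------------------------------
# Heterogeneity
# ---------------------------------------------------------------------------

def _dl_brute(y, v):
    """Textbook DerSimonian-Laird, written independently of the library path."""
    w = [1 / vi for vi in v]
    ybar = sum(wi * yi for wi, yi in zip(w, y)) / sum(w)
    q = sum(wi * (yi - ybar) ** 2 for wi, yi in zip(w, y))
    df = len(y) - 1
    c = sum(w) - sum(wi**2 for wi in w) / sum(w)
    tau2 = max(0.0, (q - df) / c)
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return q, tau2, i2


def test_dl_identical_effects_zero():
    est = dl_heterogeneity([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])
    assert est.tau2 == 0.0 and est.i2_dl == 0.0 and est.q == pytest.approx(0.0)


def test_dl_three_study_hand_computation():
    est = dl_heterogeneity([0.0, 1.0, 2.0], [1.0, 1.0, 1.0])
    assert est.q == pytest.approx(2.0)
    assert est.tau2 == 0.0
    assert est.i2_dl == 0.0


def test_dl_matches_brute_force_oracle():
    rng = np.random.default_rng(11)
    for _ in range(100):
        y = rng.normal(0, 2, size=5)
        v = rng.uniform(0.05, 2.0, size=5)
        est = dl_heterogeneity(y, v)
        q, tau2, i2 = _dl_brute(list(y), list(v))
        assert est.q == pytest.approx(q, abs=1e-10)
        assert est.tau2 == pytest.approx(tau2, abs=1e-10)
        assert est.i2_dl == pytest.approx(i2, abs=1e-10)


def test_dl_i2_shrinks_with_variance_scaling():
    y = [0.0, 0.5, 1.2, -0.4]
    v = [0.05, 0.08, 0.06, 0.07]
    i2 = [dl_heterogeneity(y, [vi * k for vi in v]).i2_dl for k in (1, 5, 25, 125)]
    assert all(b <= a for a, b in zip(i2, i2[1:]))
    assert i2[-1] == 0.0


def test_dl_requires_two_studies():
    with pytest.raises(ValueError):
        dl_heterogeneity([1.0], [0.5])


def test_dl_qprofile_ci_brackets_estimate():
    rng = np.random.default_rng(4)
    y = rng.normal(0, 1.5, size=8)
    v = rng.uniform(0.1, 0.5, size=8)
    est = dl_heterogeneity(y, v)
    lo, hi = est.ci_tau2
    assert lo <= est.tau2 + 1e-9 and est.tau2 <= hi + 1e-9 or est.tau2 == 0.0
    assert lo <= hi


def test_dl_bt_backend_unimplemented():
    with pytest.raises(NotImplementedError):
        dl_heterogeneity([0, 1], [1, 1], ci_method="biggerstaff_tweedie")


# ---------------------------------------------------------------------------
# MAP predictive intervals
# ---------------------------------------------------------------------------

def test_map_reduces_to_pooled_ci_at_zero_tau():
    m = map_predictive_interval(math.log(0.12 / 0.88), 0.2, 0.0)
    lo = 1 / (1 + math.exp(-(math.log(0.12 / 0.88) - 1.959963984540054 * 0.2)))
    assert m.lo95 == pytest.approx(lo, rel=1e-9)


def test_map_width_monotone_in_tau2():
    widths = [
        (lambda m: m.hi95 - m.lo95)(map_predictive_interval(-2.0, 0.2, t))
        for t in (0.0, 0.05, 0.2, 1.0, 10.0)
    ]
    assert all(b >= a for a, b in zip(widths, widths[1:]))
    big = map_predictive_interval(-2.0, 0.2, 1e6)
    assert big.lo95 < 1e-6 and big.hi95 > 1 - 1e-6


def test_map_asymmetry_on_proportion_scale():
    """Inverse-logit convexity below p = 0.5: upper arm longer than lower."""
    m = map_predictive_interval(math.log(0.12 / 0.88), 0.35, 0.03)
    assert m.point == pytest.approx(0.12, abs=1e-9)
    assert (m.hi95 - m.point) > (m.point - m.lo95)
    assert 0.0 < m.lo95 < m.point < m.hi95 < 1.0


def test_map_domain():
    with pytest.raises(ValueError):
        map_predictive_interval(0.0, 0.1, 0.1, level=1.5)


# ---------------------------------------------------------------------------
# Pooled summaries, meta-regression
# ---------------------------------------------------------------------------

ETDS = (-23.2, -11.8, -17.3, -10.4, -10.5, -7.8)
NS = (17, 16, 2108, 904, 31, 101)


def _effects():
    return [EffectEstimate(f"s{i}", e, 0.5, n) for i, (e, n) in enumerate(zip(ETDS, NS))]


def test_pooled_summary_published_values():
    ps = pooled_summary(_effects())
    assert ps.unweighted_mean == pytest.approx(-13.50, abs=0.005)
    assert ps.sd == pytest.approx(5.70, abs=0.005)
    assert ps.weighted_mean == pytest.approx(-14.97, abs=0.005)
    assert ps.cv_percent == pytest.approx(42.2, abs=0.05)


def test_pooled_summary_weighted_mean_bounded():
    ps = pooled_summary(_effects())
    assert min(ETDS) <= ps.weighted_mean <= max(ETDS)


def test_pooled_summary_identical_effects():
    ps = pooled_summary([EffectEstimate(str(i), -5.0, 0.5, 10) for i in range(3)])
    assert ps.sd == 0.0 and ps.cv_percent == 0.0


def test_meta_regression_published_p_values():
    # published row: r = 0.692 with 6 trials -> p = 0.128
    r, n = 0.692, 6
    t = r * math.sqrt(n - 2) / math.sqrt(1 - r * r)
    from scipy import stats as ss
    assert 2 * ss.t.sf(t, n - 2) == pytest.approx(0.128, abs=0.002)
    # library path on synthetic pairs realizing the same r
    x = np.arange(6.0)
    y = r * (x - x.mean()) / x.std() + math.sqrt(1 - r * r) * np.array(
        [0.3, -1.2, 0.8, -0.1, 0.9, -0.7])
    got = meta_regression_corr(x, y)
    t2 = got["r"] * math.sqrt(4) / math.sqrt(1 - got["r"] ** 2)
    assert got["p_value"] == pytest.approx(2 * ss.t.sf(abs(t2), 4), rel=1e-9)


def test_meta_regression_r_0382_p_045():
    """r = 0.382 with n = 6 gives p about 0.45, matching the published row."""
    from scipy import stats as ss
    r = 0.382
    t = r * math.sqrt(4) / math.sqrt(1 - r * r)
    assert 2 * ss.t.sf(t, 4) == pytest.approx(0.45, abs=0.01)


def test_meta_regression_perfect_line():
    got = meta_regression_corr([1, 2, 3, 4], [2, 4, 6, 8])
    assert got["r"] == pytest.approx(1.0)
    assert got["p_value"] == pytest.approx(0.0, abs=1e-12)


def test_meta_regression_degenerate():
    with pytest.raises(ValueError):
        meta_regression_corr([1, 1, 1], [1, 2, 3])


# ---------------------------------------------------------------------------
# Transport weights, E-values
# ---------------------------------------------------------------------------

def test_transport_weight_max_at_target():
    recs = [{"age": a, "bmi": b} for a, b in [(40, 30), (50, 36), (60, 42)]]
    w = transport_weights(recs, {"age": 50, "bmi": 36}, np.diag([25.0, 9.0]))
    assert np.argmax(w) == 1
    assert w.mean() == pytest.approx(1.0)


def test_transport_weights_identical_records():
    recs = [{"age": 50.0}] * 5
    w = transport_weights(recs, {"age": 55.0}, np.array([[16.0]]))
    assert np.allclose(w, 1.0)


def test_transport_weights_quadratic_form_oracle():
    recs = [{"x": 1.0, "y": 0.0}, {"x": 0.0, "y": 2.0}]
    cov = np.array([[2.0, 0.5], [0.5, 1.0]])
    w = transport_weights(recs, {"x": 0.0, "y": 0.0}, cov)
    inv = np.linalg.inv(cov)
    d2 = [np.array([1, 0]) @ inv @ np.array([1, 0]),
          np.array([0, 2]) @ inv @ np.array([0, 2])]
    raw = np.exp(-0.5 * np.array(d2))
    expect = raw / raw.mean()
    assert np.allclose(w, expect)


def test_transport_weights_singular_cov():
    with pytest.raises(ValueError, match="singular"):
        transport_weights([{"x": 1.0, "y": 1.0}], {"x": 0.0, "y": 0.0},
                          np.array([[1.0, 1.0], [1.0, 1.0]]))


def test_e_value():
    assert e_value(1.0) == pytest.approx(1.0)
    assert e_value(2.0) == pytest.approx(2 + math.sqrt(2))
    assert e_value(0.5) == pytest.approx(e_value(2.0))  # inversion symmetry
    with pytest.raises(ValueError):
        e_value(0.0)
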