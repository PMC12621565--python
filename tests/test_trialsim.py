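"""Design operating characteristics: power, boundaries, SSR, retention."""

import math

import numpy as np
import pytest

from synthtte.trialsim import (
    DesignSpec,
    completion_curve,
    expected_sample_size,
    gsd_boundaries,
    power_equivalence,
    power_noninferiority,
    power_two_arm,
    sample_size_reestimation,
    sd_from_se,
    se_of_difference,
    simulate_h2h,
)

SE_TRIPLETS = [
    (0.283, (0.200, 0.163)),   # phase-III obesity scale
    (0.297, (0.210, 0.172)),   # diabetes-population row
    (0.673, (0.476, 0.389)),   # early-phase scale
]


# ---------------------------------------------------------------------------
# SE scaling
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("se500,targets", SE_TRIPLETS)
def test_se_scaling_published_triplets(se500, targets):
    sd = sd_from_se(se500, 500)
    assert se_of_difference(sd, 1000) == pytest.approx(targets[0], abs=0.001)
    assert se_of_difference(sd, 1500) == pytest.approx(targets[1], abs=0.001)


def test_se_quadrupling_halves():
    sd = 9.0
    assert se_of_difference(sd, 400) == pytest.approx(se_of_difference(sd, 100) / 2)


# ---------------------------------------------------------------------------
# Power
# ---------------------------------------------------------------------------

def test_power_large_effect_saturates():
    sd = sd_from_se(0.283, 500)
    oc = power_two_arm(DesignSpec(effect=17.3, sd=sd, n_per_arm=500))
    assert oc.power > 0.999
    assert oc.se_effect == pytest.approx(0.283, abs=1e-9)


def test_power_null_design():
    with pytest.warns(UserWarning, match="null design"):
        oc = power_two_arm(DesignSpec(effect=0.0, sd=5.0, n_per_arm=100))
    assert oc.power == pytest.approx(0.05, abs=1e-9)  # both tails at the null


def test_power_half_at_boundary_effect():
    sd, n = 6.0, 80
    se = se_of_difference(sd, n)
    eff = 1.959963984540054 * se
    oc = power_two_arm(DesignSpec(effect=eff, sd=sd, n_per_arm=n))
    assert oc.power == pytest.approx(0.5, abs=1e-4)


def test_power_monotone_in_n_effect_margin():
    p_n = [power_two_arm(DesignSpec(effect=2.0, sd=8.0, n_per_arm=n)).power
           for n in (50, 100, 400, 1000)]
    assert all(b > a for a, b in zip(p_n, p_n[1:]))
    p_e = [power_two_arm(DesignSpec(effect=e, sd=8.0, n_per_arm=200)).power
           for e in (0.5, 1.0, 2.0, 4.0)]
    assert all(b > a for a, b in zip(p_e, p_e[1:]))
    p_m = [power_noninferiority(DesignSpec(effect=0.0, sd=8.0, n_per_arm=600,
                                           margin=m)).power
           for m in (1.0, 2.0, 3.0, 5.0)]
    assert all(b > a for a, b in zip(p_m, p_m[1:]))


def test_noninferiority_boundary_power_alpha():
    spec = DesignSpec(effect=-2.0, sd=8.0, n_per_arm=600, margin=2.0)
    oc = power_noninferiority(spec)
    assert oc.power == pytest.approx(0.025, abs=1e-9)


def test_noninferiority_bracket_published_pair():
    """A plausible sd puts the 2/3 pp margin powers astride 85.2/94.8 % at
    600 per arm, and the larger margin always wins."""
    for sd in (7.5, 8.0, 8.5):
        p2 = power_noninferiority(DesignSpec(effect=0.4, sd=sd, n_per_arm=600, margin=2.0)).power
        p3 = power_noninferiority(DesignSpec(effect=0.4, sd=sd, n_per_arm=600, margin=3.0)).power
        assert p3 > p2


def test_noninferiority_margin_required():
    with pytest.raises(ValueError):
        power_noninferiority(DesignSpec(effect=1.0, sd=5.0, n_per_arm=100))


def test_equivalence_tost():
    oc = power_equivalence(DesignSpec(effect=0.0, sd=6.0, n_per_arm=500, margin=2.0))
    assert 0.0 < oc.power <= 1.0
    worse = power_equivalence(DesignSpec(effect=1.5, sd=6.0, n_per_arm=500, margin=2.0))
    assert worse.power < oc.power


# ---------------------------------------------------------------------------
# Group-sequential boundaries
# ---------------------------------------------------------------------------

def test_gsd_two_look_obf():
    b = gsd_boundaries(alpha=0.05, info_fractions=(0.5, 1.0), spending="obf")
    z = b.z_boundaries
    assert round(z[0], 2) == 2.96
    assert round(z[1], 2) == 1.97
    assert b.looks[-1]["alpha_spent"] == pytest.approx(0.025, abs=1e-12)


def test_gsd_single_look_reduces_to_fixed():
    b = gsd_boundaries(alpha=0.05, info_fractions=(1.0,))
    assert b.z_boundaries[0] == pytest.approx(1.959963984540054, abs=2e-4)


def test_gsd_alpha_conservation():
    """Cumulative spend hits alpha/2 per side within numerical tolerance."""
    b = gsd_boundaries(alpha=0.05, info_fractions=(0.25, 0.5, 0.75, 1.0))
    spent = [lk["alpha_spent"] for lk in b.looks]
    assert all(s2 >= s1 for s1, s2 in zip(spent, spent[1:]))
    assert spent[-1] == pytest.approx(0.025, abs=1e-6)


def test_gsd_obf_boundaries_decrease():
    b = gsd_boundaries(alpha=0.05, info_fractions=(0.25, 0.5, 0.75, 1.0))
    z = b.z_boundaries
    assert all(b2 < b1 for b1, b2 in zip(z, z[1:]))


def test_gsd_pocock_flatter_than_obf():
    obf = gsd_boundaries(spending="obf", info_fractions=(0.5, 1.0)).z_boundaries
    poc = gsd_boundaries(spending="pocock", info_fractions=(0.5, 1.0)).z_boundaries
    assert poc[0] < obf[0]          # Pocock spends more early
    assert poc[1] > obf[1]


def test_gsd_invalid_fractions():
    with pytest.raises(ValueError):
        gsd_boundaries(info_fractions=(0.5, 0.4, 1.0))
    with pytest.raises(ValueError):
        gsd_boundaries(info_fractions=(0.5, 0.9))


# ---------------------------------------------------------------------------
# Expected sample size, SSR
# ---------------------------------------------------------------------------

def test_expected_sample_size_definitional():
    assert expected_sample_size([800, 1600], [1.0, 0.0]) == 800
    assert expected_sample_size([800, 1600], [0.0, 1.0]) == 1600
    # 0.15*800 + 0.85*1600 = 1480
    assert expected_sample_size([800, 1600], [0.15, 0.85]) == pytest.approx(1480)


def test_expected_sample_size_bounded_by_max():
    n = [400, 900, 1600]
    p = [0.2, 0.3, 0.5]
    assert expected_sample_size(n, p) <= max(n)


def test_expected_sample_size_invalid_probs():
    with pytest.raises(ValueError):
        expected_sample_size([800, 1600], [0.4, 0.4])


def test_ssr_no_change_at_design_effect():
    """Interim estimate equal to the (adequately powered) design effect
    keeps the planned size."""
    sd, n_plan = 8.0, 500
    se = se_of_difference(sd, n_plan)
    design_effect = (1.959963984540054 + 0.8416212335729143) * se  # 80 % power
    n_new = sample_size_reestimation(design_effect, se, 0.80,
                                     planned_n_per_arm=n_plan)
    assert n_new == n_plan


def test_ssr_inflation_capped():
    sd, n_plan = 8.0, 500
    se = se_of_difference(sd, n_plan)
    design_effect = (1.959963984540054 + 0.8416212335729143) * se
    n_new = sample_size_reestimation(design_effect / 2, se, 0.80,
                                     planned_n_per_arm=n_plan, max_inflation=2.0)
    assert n_new == 2 * n_plan
    n_cap1 = sample_size_reestimation(design_effect / 2, se, 0.80,
                                      planned_n_per_arm=n_plan, max_inflation=1.0)
    assert n_cap1 == n_plan


def test_ssr_invalid_inputs():
    with pytest.raises(ValueError):
        sample_size_reestimation(1.0, 0.0, 0.8)
    with pytest.raises(ValueError):
        sample_size_reestimation(1.0, 0.5, 0.8, max_inflation=0.5)


# ---------------------------------------------------------------------------
# Completion curves
# ---------------------------------------------------------------------------

def test_completion_no_dropout():
    curve = completion_curve(0.0, horizon=68)
    assert all(v == 1.0 for v in curve.values())


def test_completion_anniversary_anchor():
    curve = completion_curve(0.15, weeks=np.array([0.0, 52.0, 68.0]))
    assert curve[0.0] == 1.0
    assert curve[52.0] == pytest.approx(0.85, abs=1e-12)
    assert curve[68.0] == pytest.approx(math.exp(68 * math.log(0.85) / 52), abs=1e-12)
    assert curve[68.0] == pytest.approx(0.808, abs=0.001)


def test_completion_extra_hazards_monotone():
    base = completion_curve(0.15, horizon=68)
    extra = completion_curve(0.15, {"early_term": 0.025, "deviation": 0.05}, horizon=68)
    for w in base:
        assert extra[w] <= base[w]
    vals = list(extra.values())
    assert all(b <= a for a, b in zip(vals, vals[1:]))


def test_completion_domain():
    with pytest.raises(ValueError):
        completion_curve(1.0)


# ---------------------------------------------------------------------------
# Virtual head-to-head
# ---------------------------------------------------------------------------

def test_h2h_deterministic():
    specs = [{"mean": -21.2, "sd": 9.7, "n": 100}, {"mean": -20.9, "sd": 9.7, "n": 100}]
    a = simulate_h2h(specs, n_replicates=200, seed=7)
    b = simulate_h2h(specs, n_replicates=200, seed=7)
    assert np.array_equal(a["differences"], b["differences"])


def test_h2h_noninferiority_mostly_concluded():
    """Near-equal arms at phase-III scale: NI at a 1.5 pp margin concluded
    in the large majority of replicates."""
    specs = [{"mean": -21.2, "sd": 9.7, "n": 850}, {"mean": -20.9, "sd": 9.7, "n": 850}]
    res = simulate_h2h(specs, n_replicates=400, seed=11, ni_margin=1.5)
    assert res["rejection_rate"] > 0.5
    mean_diff = res["differences"].mean()
    assert mean_diff == pytest.approx(-0.3, abs=0.1)


def test_h2h_dropout_reduces_precision():
    specs0 = [{"mean": 0.0, "sd": 9.0, "n": 200}, {"mean": 0.0, "sd": 9.0, "n": 200}]
    specs1 = [{"mean": 0.0, "sd": 9.0, "n": 200, "dropout": 0.5},
              {"mean": 0.0, "sd": 9.0, "n": 200, "dropout": 0.5}]
    r0 = simulate_h2h(specs0, n_replicates=300, seed=3)
    r1 = simulate_h2h(specs1, n_replicates=300, seed=3)
    assert r1["se"].mean() > r0["se"].mean()


def test_h2h_arg_validation():
    with pytest.raises(ValueError):
        simulate_h2h([{"mean": 0, "sd": 1, "n": 10}], n_replicates=10)
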