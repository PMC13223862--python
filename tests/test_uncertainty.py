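"""Distribution calibration, PSA behavior, CEAC and tornado analysis."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

import tsacea
from tsacea.synthetic import shrink_ranges
from tsacea.uncertainty import PSAResult


def test_beta_calibration_recovers_published_utility_moments():
    d = tsacea.beta_from_mean_range(0.87, 0.78, 0.96)
    assert d.kind == "beta"
    assert d.a == pytest.approx(45.8, abs=0.05)
    assert d.b == pytest.approx(6.85, abs=0.05)
    assert d.a / (d.a + d.b) == pytest.approx(0.87, abs=1e-9)
    assert d.sd == pytest.approx((0.96 - 0.78) / 3.92, abs=1e-9)


def test_symmetric_beta_has_equal_shapes():
    d = tsacea.beta_from_mean_range(0.5, 0.3, 0.7)
    assert d.a == pytest.approx(d.b, rel=1e-12)


def test_beta_rejects_too_wide_range():
    with pytest.raises(ValueError, match="too wide"):
        tsacea.beta_from_mean_range(0.01, 0.0, 0.9)


def test_gamma_calibration_recovers_cost_moments():
    d = tsacea.gamma_from_mean_range(16_941, 13_553, 20_329)
    assert d.kind == "gamma"
    assert d.a == pytest.approx(96.1, abs=0.1)
    assert d.b == pytest.approx(176.4, abs=0.1)
    se = (20_329 - 13_553) / 3.92
    assert d.a * d.b == pytest.approx(16_941, rel=1e-9)
    assert d.a * d.b**2 == pytest.approx(se**2, rel=1e-6)


@given(
    mean=st.floats(min_value=10.0, max_value=1e5),
    spread=st.floats(min_value=0.01, max_value=0.5),
)
def test_gamma_mean_identity_property(mean, spread):
    d = tsacea.gamma_from_mean_range(mean, mean * (1 - spread), mean * (1 + spread))
    assert d.a * d.b == pytest.approx(mean, rel=1e-9)


@given(
    mean=st.floats(min_value=0.05, max_value=0.95),
    spread=st.floats(min_value=0.005, max_value=0.04),
)
def test_beta_mean_identity_property(mean, spread):
    d = tsacea.beta_from_mean_range(mean, mean - spread, mean + spread)
    assert d.a / (d.a + d.b) == pytest.approx(mean, rel=1e-9)


def test_fitted_beta_sampling_mean(rng):
    d = tsacea.beta_from_mean_range(0.87, 0.78, 0.96)
    x = d.sample(rng, 1_000_000)
    se = x.std(ddof=1) / 1000.0
    assert abs(x.mean() - 0.87) <= 3 * se
    # agreement with the scipy parameterization of the same fit
    assert scipy.stats.beta(d.a, d.b).mean() == pytest.approx(0.87, abs=1e-12)


def test_zero_width_range_is_point_mass(rng):
    d = tsacea.gamma_from_mean_range(100.0, 100.0, 100.0)
    assert d.kind == "point"
    assert np.all(d.sample(rng, 5) == 100.0)


def test_same_seed_psa_is_bit_identical(published_inputs, us_lt):
    arms, utilities, cfg = published_inputs
    a = tsacea.run_psa(arms, utilities, cfg, us_lt, n_iterations=50, seed=3)
    b = tsacea.run_psa(arms, utilities, cfg, us_lt, n_iterations=50, seed=3)
    pd.testing.assert_frame_equal(a.draws, b.draws)
    assert a.summary() == b.summary()


def test_zero_variance_psa_collapses_to_base_case(published_inputs, us_lt):
    arms, utilities, cfg = published_inputs
    tight_arms, tight_util = shrink_ranges(arms, utilities, 0.0)
    base = tsacea.compare_arms(tight_arms, tight_util, cfg, us_lt)
    psa = tsacea.run_psa(tight_arms, tight_util, cfg, us_lt, n_iterations=20, seed=0)
    assert np.allclose(psa.draws["delta_cost"], base.delta_cost, atol=1e-9)
    assert np.allclose(psa.draws["delta_qaly"], base.delta_qaly, atol=1e-12)
    assert psa.proportion_dominant in (0.0, 1.0)


def test_dominant_draws_are_cost_effective_subset(published_inputs, us_lt):
    arms, utilities, cfg = published_inputs
    psa = tsacea.run_psa(arms, utilities, cfg, us_lt, n_iterations=500, seed=11)
    d = psa.draws
    assert d.loc[d["dominant"], "cost_effective"].all()
    assert psa.proportion_dominant <= psa.proportion_cost_effective
    assert len(d) == 500
    assert sum(psa.quadrant_counts.values()) == 500


def fake_psa(dc, dq, wtp=100_000.0):
    dc = np.asarray(dc, dtype=float)
    dq = np.asarray(dq, dtype=float)
    inmb = wtp * dq - dc
    draws = pd.DataFrame(
        {
            "iter": np.arange(len(dc)),
            "delta_cost": dc,
            "delta_qaly": dq,
            "inmb": inmb,
            "quadrant": "SE",
            "dominant": (dc < 0) & (dq > 0),
            "cost_effective": inmb > 0,
        }
    )
    return PSAResult(
        draws=draws,
        wtp=wtp,
        seed=0,
        n_iterations=len(dc),
        mean_delta_cost=dc.mean(),
        mean_delta_qaly=dq.mean(),
        ui_delta_cost=(dc.min(), dc.max()),
        ui_delta_qaly=(dq.min(), dq.max()),
        proportion_cost_effective=float((inmb > 0).mean()),
        proportion_dominant=float(((dc < 0) & (dq > 0)).mean()),
        quadrant_counts={},
    )


def test_ceac_consistency_and_limits():
    psa = fake_psa(dc=[-100, 50, 200, -30], dq=[0.01, 0.002, -0.001, 0.0])
    curve = tsacea.ceac(psa, [0, 100_000])
    # at wtp 0 the INMB reduces to -delta_cost
    assert curve["probability_cost_effective"][0] == pytest.approx(0.5)
    assert curve["probability_cost_effective"][1] == psa.proportion_cost_effective
    assert tsacea.ceac(psa, []).empty


def test_ceac_monotone_when_dq_has_one_sign(rng):
    dq = rng.uniform(0.001, 0.02, size=200)
    dc = rng.normal(0, 2000, size=200)
    curve = tsacea.ceac(fake_psa(dc, dq), np.linspace(0, 200_000, 21))
    assert np.all(np.diff(curve["probability_cost_effective"]) >= 0)


def test_tornado_ranking_and_shared_parameters(published_inputs, us_lt):
    arms, utilities, cfg = published_inputs
    tor = tsacea.run_tornado(arms, utilities, cfg, us_lt)
    t = tor.table
    assert list(t["rank"]) == sorted(t["rank"])
    assert t["swing"].is_monotonic_decreasing
    assert (t["swing"] >= 0).all()
    # a cycle-0 primary cost's INMB swing equals its range width exactly
    row = t.set_index("parameter").loc["inpatient primary cost"]
    assert row["swing"] == pytest.approx(24_701 - 16_467, abs=1e-6)
    row = t.set_index("parameter").loc["outpatient primary cost"]
    assert row["swing"] == pytest.approx(20_329 - 13_553, abs=1e-6)


def test_tornado_zero_width_range_gives_zero_swing(published_inputs, us_lt):
    arms, utilities, cfg = published_inputs
    tight_arms, tight_util = shrink_ranges(arms, utilities, 0.0)
    tor = tsacea.run_tornado(tight_arms, tight_util, cfg, us_lt)
    assert np.allclose(tor.table["swing"], 0.0, atol=1e-9)


def test_cycle0_cost_swing_identity_on_synthetic_set(us_lt):
    """For any parameter entering only as an undiscounted cycle-0 cost of one
    arm, the tornado swing equals the range width analytically."""
    (arms, utilities, _) = tsacea.make_parameter_set(seed=5, perturbation_scale=0.1)[:3]
    cfg = tsacea.load_published_parameters()[2]
    tor = tsacea.run_tornado(arms, utilities, cfg, us_lt)
    t = tor.table.set_index("parameter")
    for label, arm in (("outpatient", arms[0]), ("inpatient", arms[1])):
        width = arm.c_primary.high - arm.c_primary.low
        assert t.loc[f"{label} primary cost", "swing"] == pytest.approx(
            width, rel=1e-9
        )
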