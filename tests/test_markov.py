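"""Engine correctness: transition structure, accounting, and oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import tsacea
from tsacea.markov import State
from tsacea.parameters import Ranged, RunConfig, StrategyParams, UtilitySet


def make_arm(
    label="test",
    start_age=66.0,
    c_primary=10_000.0,
    c_readmission=4_000.0,
    c_revision=40_000.0,
    p_readmit=0.04,
    p_rev=0.04,
):
    return StrategyParams(
        label=label,
        start_age=Ranged.point(start_age),
        c_primary=Ranged.point(c_primary),
        c_readmission=Ranged.point(c_readmission),
        c_revision=Ranged.point(c_revision),
        p_readmission_90d=Ranged.point(p_readmit),
        p_revision_total=Ranged.point(p_rev),
    )


def make_utilities(u_well=0.87, u_post=0.75, u_acute=0.52):
    return UtilitySet(
        u_well=Ranged.point(u_well),
        u_post_revision=Ranged.point(u_post),
        u_acute_event=Ranged.point(u_acute),
    )


@pytest.mark.parametrize(
    "p, n, expected, tol",
    [(0.0, 3, 0.0, 0), (1.0, 3, 1.0, 0), (0.052, 3, 0.01764, 5e-6)],
)
def test_per_cycle_from_window_examples(p, n, expected, tol):
    got = tsacea.per_cycle_from_window(p, n)
    assert got == pytest.approx(expected, abs=tol)
    # compounding inverts exactly
    assert 1.0 - (1.0 - got) ** n == pytest.approx(p, abs=1e-12)


@pytest.mark.parametrize(
    "cycle, rate, expected",
    [(0, 0.03, 1.0), (12, 0.03, 1 / 1.03), (240, 0.03, 1.03**-20)],
)
def test_discount_factor(cycle, rate, expected):
    assert tsacea.discount_factor(cycle, rate) == pytest.approx(expected, rel=1e-12)


@given(
    p_readmit=st.floats(min_value=0.0, max_value=1.0),
    p_rev=st.floats(min_value=0.0, max_value=1.0),
    qx=st.floats(min_value=0.0, max_value=1.0),
    cycle=st.integers(min_value=0, max_value=239),
)
def test_transition_matrix_is_row_stochastic(p_readmit, p_rev, qx, cycle):
    law = tsacea.SyntheticMortalityLaw(
        law="constant_hazard", qx=qx, age_min=40, age_max=130
    )
    lt = tsacea.make_life_table(law)
    arm = make_arm(p_readmit=p_readmit, p_rev=p_rev)
    cfg = RunConfig(revision_spread_mode="annual")
    M = tsacea.transition_matrix(arm, make_utilities(), cfg, lt, cycle)
    assert np.allclose(M.sum(axis=1), 1.0, atol=1e-12)
    assert np.all(M >= 0)
    # absorbing death, no tunnel self-loops
    assert M[State.DEATH].tolist() == [0, 0, 0, 0, 1]
    assert M[State.READMIT_TUNNEL, State.READMIT_TUNNEL] == 0
    assert M[State.REVISION_TUNNEL, State.REVISION_TUNNEL] == 0


def test_single_active_hazard_row(immortal_lt):
    """No mortality, beyond the perioperative window: WELL row is (1-h,0,h,0,0)."""
    arm = make_arm(p_rev=0.3)
    cfg = RunConfig(revision_spread_mode="annual")
    h = tsacea.per_cycle_from_window(0.3, 12)
    M = tsacea.transition_matrix(arm, make_utilities(), cfg, immortal_lt, cycle=10)
    assert M[State.WELL].tolist() == pytest.approx([1 - h, 0, h, 0, 0], abs=1e-15)


def test_pure_well_cohort_accrues_utility_times_years(immortal_lt):
    """No mortality, no events, no discounting: QALYs = u_well * years."""
    arm = make_arm(p_readmit=0.0, p_rev=0.0, c_primary=5000.0)
    cfg = RunConfig(horizon_years=1, discount_rate_annual=0.0)
    trace = tsacea.run_cohort(arm, make_utilities(), cfg, immortal_lt)
    assert trace.total_qalys == pytest.approx(0.87, rel=1e-12)
    assert trace.total_cost == pytest.approx(5000.0, rel=1e-12)


@pytest.mark.parametrize("half_cycle", [False, True])
@pytest.mark.parametrize("cycle0", [False, True])
def test_constant_hazard_geometric_oracle(flat_lt, half_cycle, cycle0):
    """Event-free cohort under constant qx matches the closed form to 1e-9."""
    arm = make_arm(p_readmit=0.0, p_rev=0.0)
    cfg = RunConfig(half_cycle_correction=half_cycle, cycle0_utility=cycle0)
    trace = tsacea.run_cohort(arm, make_utilities(), cfg, flat_lt)
    expected = tsacea.constant_hazard_qale(
        qx=0.02,
        utility=0.87,
        horizon_years=20,
        annual_rate=0.03,
        half_cycle=half_cycle,
        cycle0_utility=cycle0,
    )
    assert trace.total_qalys == pytest.approx(expected, rel=1e-9)
    assert trace.total_cost == pytest.approx(arm.c_primary.base, rel=1e-12)


@given(
    p_readmit=st.floats(min_value=0.0, max_value=1.0),
    p_rev=st.floats(min_value=0.0, max_value=1.0),
    qx=st.floats(min_value=0.0, max_value=0.5),
)
def test_occupancy_conserved_and_death_monotone(p_readmit, p_rev, qx):
    law = tsacea.SyntheticMortalityLaw(
        law="constant_hazard", qx=qx, age_min=40, age_max=130
    )
    lt = tsacea.make_life_table(law)
    arm = make_arm(p_readmit=p_readmit, p_rev=p_rev)
    cfg = RunConfig(horizon_years=5, revision_spread_mode="annual")
    trace = tsacea.run_cohort(arm, make_utilities(), cfg, lt)
    assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-10)
    assert np.all(np.diff(trace.occupancy[:, State.DEATH]) >= -1e-15)
    assert np.all(trace.cycle_costs >= 0)
    assert np.all(trace.cycle_qalys >= 0)


def test_totals_monotone_in_costs_utilities_and_mortality(us_lt):
    base_arm = make_arm()
    base_u = make_utilities()
    cfg = RunConfig(revision_spread_mode="annual")
    ref = tsacea.run_cohort(base_arm, base_u, cfg, us_lt)
    pricier = make_arm(c_revision=60_000.0)
    assert (
        tsacea.run_cohort(pricier, base_u, cfg, us_lt).total_cost > ref.total_cost
    )
    happier = make_utilities(u_post=0.85)
    assert (
        tsacea.run_cohort(base_arm, happier, cfg, us_lt).total_qalys
        > ref.total_qalys
    )
    deadlier = tsacea.make_life_table(
        tsacea.SyntheticMortalityLaw(
            law="constant_hazard", qx=0.10, age_min=40, age_max=130
        )
    )
    worse = tsacea.run_cohort(base_arm, base_u, cfg, deadlier)
    assert worse.total_cost < ref.total_cost
    assert worse.total_qalys < ref.total_qalys


def test_tunnel_occupancy_equals_entering_mass(us_lt):
    """Mass entering a tunnel occupies it for exactly one accounting step."""
    arm = make_arm(p_readmit=0.3, p_rev=0.2)
    cfg = RunConfig(horizon_years=2, revision_spread_mode="annual")
    u = make_utilities()
    trace = tsacea.run_cohort(arm, u, cfg, us_lt)
    occ = trace.occupancy
    for t in range(1, trace.n_cycles + 1):
        M = tsacea.transition_matrix(arm, u, cfg, us_lt, t - 1)
        expected_rt = occ[t - 1, State.WELL] * M[State.WELL, State.READMIT_TUNNEL]
        assert occ[t, State.READMIT_TUNNEL] == pytest.approx(expected_rt, abs=1e-14)
    # tunnels drain completely after the window closes and revision stops
    assert occ[-1, State.READMIT_TUNNEL] < 0.25  # only most recent entrants


def test_batch_matches_scalar_bit_for_bit(published_inputs, us_lt):
    (op, ip), utilities, cfg = published_inputs
    trace = tsacea.run_cohort(op, utilities, cfg, us_lt)
    costs, qalys = tsacea.run_cohort_batch(
        op,
        cfg,
        us_lt,
        c_primary=np.full(3, op.c_primary.base),
        c_readmission=op.c_readmission.base,
        c_revision=op.c_revision.base,
        p_readmission=op.p_readmission_90d.base,
        p_revision=np.full(3, op.p_revision_total.base),
        u_well=utilities.u_well.base,
        u_post=utilities.u_post_revision.base,
        u_acute=utilities.u_acute_event.base,
    )
    assert np.all(costs == trace.total_cost)
    assert np.all(qalys == trace.total_qalys)


def test_microsimulation_agrees_with_cohort_expectation(published_inputs, us_lt):
    """10^5 individual walkers through the same matrices reproduce the cohort
    totals within 3 Monte-Carlo standard errors."""
    (op, _), utilities, cfg = published_inputs
    trace = tsacea.run_cohort(op, utilities, cfg, us_lt)
    sim = tsacea.simulate_individuals(
        op, utilities, cfg, us_lt, n_walkers=100_000, seed=7
    )
    assert abs(sim["mean_cost"] - trace.total_cost) <= 3 * sim["se_cost"]
    assert abs(sim["mean_qalys"] - trace.total_qalys) <= 3 * sim["se_qalys"]


def test_trace_export_columns(published_inputs, us_lt, tmp_path):
    (op, _), utilities, cfg = published_inputs
    trace = tsacea.run_cohort(op, utilities, cfg, us_lt)
    df = trace.to_frame()
    assert list(df.columns) == [
        "cycle", "age", "p_well", "p_readmit", "p_rev_tunnel", "p_postrev",
        "p_death", "cost_disc", "qaly_disc",
    ]
    assert len(df) == cfg.horizon_cycles + 1
    assert df["cost_disc"].sum() == pytest.approx(trace.total_cost)


def test_zero_horizon_rejected():
    with pytest.raises(ValueError):
        RunConfig(horizon_years=0)
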