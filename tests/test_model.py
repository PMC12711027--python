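"""Competition-model unit and property tests."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plasmidcomp.model import (
    NO_REPLACEMENT,
    ModelParams,
    PopulationState,
    ReplacementCriterion,
    derivatives,
    force_of_infection,
    load_scenario,
    replacement_time,
    simulate,
    simulate_serial_transfer,
    single_plasmid_equilibrium,
    standard_initial_state,
    sweep_advantages,
    sweep_influx,
    sweep_parameter,
)


class TestForceOfInfection:
    @pytest.mark.parametrize(
        "state, beta_W, beta_M, expected",
        [
            (PopulationState(0, 0.89, 0, 0.01), 1.0, 1.0, (0.895, 0.005)),
            (PopulationState(0, 0, 0, 0), 1.0, 1.0, (0.0, 0.0)),
            # co-infected cells donate each variant with probability 1/2
            (PopulationState(0, 0, 0, 2.0), 3.0, 1.0, (3.0, 1.0)),
        ],
    )
    def test_matches_definition(self, state, beta_W, beta_M, expected):
        p = ModelParams(beta_W=beta_W, beta_M=beta_M)
        assert force_of_infection(state, p) == pytest.approx(expected)

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            PopulationState(NW=-0.1)


class TestDerivatives:
    def test_empty_system_is_absorbing(self, printed_params):
        zero = PopulationState(0, 0, 0, 0)
        assert derivatives(zero, printed_params) == pytest.approx([0, 0, 0, 0])

    def test_hand_computed_invasion_rates(self, printed_params, invasion_state):
        # Frozen by independent term-by-term substitution into the
        # right-hand sides before any integrator code existed.
        d = derivatives(invasion_state, printed_params)
        assert d == pytest.approx([0.0, -0.0088545, 9e-5, -0.0002355], abs=1e-12)

    def test_displacement_flux_terms(self, standard_params, invasion_state):
        # The co-infection displacement variant adds +(1-k) NWM lam_i / 2 to
        # each singly-infected compartment, balanced by losses from NWM.
        bare = derivatives(
            invasion_state, dataclasses.replace(standard_params, displacement_flux=False)
        )
        disp = derivatives(invasion_state, standard_params)
        lam_W, lam_M = force_of_infection(invasion_state, standard_params)
        add_W = (1 - standard_params.k) * 0.5 * invasion_state.NWM * lam_W
        add_M = (1 - standard_params.k) * 0.5 * invasion_state.NWM * lam_M
        assert disp[1] - bare[1] == pytest.approx(add_W)
        assert disp[2] - bare[2] == pytest.approx(add_M)
        assert disp[3] - bare[3] == pytest.approx(-(add_W + add_M))
        assert disp.sum() == pytest.approx(bare.sum())

    def test_equilibrium_is_stationary(self, standard_params):
        n_star = single_plasmid_equilibrium(standard_params)
        state = PopulationState(0, n_star, 0, 0)
        d = derivatives(state, standard_params)
        assert d[1] == pytest.approx(0.0, abs=1e-15)


class TestModelParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"rho": -1.0},
            {"c": 1.0},
            {"c": -0.1},
            {"s_W": 0.7, "s_M": 0.6},
            {"s_M": 1.5},
            {"k": 1.2},
            {"beta_W": -0.5},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)

    def test_advantage_parametrisation(self, standard_params):
        p = standard_params.with_advantages(1.7, 1.3)
        assert p.a_H == pytest.approx(1.7)
        assert p.a_V == pytest.approx(1.3)
        assert p.beta_M == pytest.approx(1.7 * p.beta_W)
        assert p.s_W == pytest.approx(1.3 * p.s_M)


class TestEquilibrium:
    def test_standard_value(self, standard_params):
        # K (1 - gamma / ((1-c) rho)) = 8/9 for the standard parameters
        assert single_plasmid_equilibrium(standard_params) == pytest.approx(8 / 9)

    def test_persistence_boundary(self):
        p = ModelParams(rho=1.0, c=0.1, gamma=0.9)
        assert single_plasmid_equilibrium(p) == 0.0

    def test_logistic_limit(self):
        p = ModelParams(K=2.0, c=0.0, gamma=0.0)
        assert single_plasmid_equilibrium(p) == pytest.approx(2.0)

    def test_extinct_warns(self):
        p = ModelParams(rho=0.5, c=0.1, gamma=0.9)
        with pytest.warns(RuntimeWarning):
            assert single_plasmid_equilibrium(p) == 0.0


class TestSimulate:
    def test_equilibrium_is_fixed_point(self, standard_params):
        n_star = single_plasmid_equilibrium(standard_params)
        traj = simulate(
            standard_params,
            PopulationState(0, n_star, 0, 0),
            t_max=100.0,
            t_eval=np.linspace(0, 100, 11),
        )
        assert np.allclose(traj.y[1], n_star, atol=1e-7)
        assert np.allclose(traj.y[[0, 2, 3]], 0.0, atol=1e-9)

    def test_neutral_symmetry(self, standard_params):
        # With a_H = a_V = 1 and NW = NM the two variants stay identical.
        init = PopulationState(N0=0.5, NW=0.2, NM=0.2, NWM=0.01)
        traj = simulate(
            standard_params, init, t_max=1000.0, t_eval=np.linspace(0, 1000, 101)
        )
        assert np.max(np.abs(traj.y[1] - traj.y[2])) < 1e-8

    @pytest.mark.parametrize("a_H, a_V", [(1.0, 1.0), (1.5, 1.0), (1.0, 1.5)])
    def test_bounded_and_nonnegative(self, standard_params, a_H, a_V):
        p = standard_params.with_advantages(a_H, a_V)
        init = standard_initial_state(p)
        traj = simulate(p, init, t_max=500.0, t_eval=np.linspace(0, 500, 51))
        assert traj.y.min() >= 0.0
        assert traj.y.sum(axis=0).max() <= max(init.total, p.K) + 1e-6

    def test_invalid_t_max(self, standard_params, invasion_state):
        with pytest.raises(ValueError):
            simulate(standard_params, invasion_state, t_max=0.0)

    def test_start_below_threshold_is_immediate_replacement(self, standard_params):
        crit = ReplacementCriterion()
        traj = simulate(
            standard_params,
            PopulationState(N0=1.0, NWM=0.001),
            t_max=10.0,
            criterion=crit,
        )
        assert traj.replacement_time == 0.0


class TestReplacementTime:
    def test_neutral_never_replaces(self, standard_params):
        t = replacement_time(standard_params, t_max=2e4)
        assert t == NO_REPLACEMENT

    def test_regression_values(self, standard_params):
        # Frozen against an independent dense-output scan (Radau rtol 1e-10,
        # dt 0.1 grid + bisection), which agreed to ~1e-8 relative.
        t_h = replacement_time(standard_params.with_advantages(2.0, 1.0))
        assert t_h == pytest.approx(2249.8988, rel=1e-3)
        t_v = replacement_time(standard_params.with_advantages(1.0, 2.0))
        assert t_v == pytest.approx(4251.8163, rel=1e-3)

    def test_faster_with_larger_advantage(self, standard_params):
        t12 = replacement_time(standard_params.with_advantages(1.2, 1.0))
        t15 = replacement_time(standard_params.with_advantages(1.5, 1.0))
        assert math.isfinite(t12) and math.isfinite(t15)
        assert t15 <= t12

    def test_criterion_modes_agree_on_classification(self, standard_params):
        dens = ReplacementCriterion(mode="absolute_density", threshold=0.01)
        freq = ReplacementCriterion(mode="relative_frequency", threshold=0.01)
        for a_H in (1.0, 1.3, 1.8):
            p = standard_params.with_advantages(a_H, 1.0)
            finite_dens = math.isfinite(replacement_time(p, dens, t_max=5e4))
            finite_freq = math.isfinite(replacement_time(p, freq, t_max=5e4))
            assert finite_dens == finite_freq

    def test_wildtype_only_criterion_configurable(self, standard_params):
        crit = ReplacementCriterion(wildtype_compartments=("NW",))
        p = standard_params.with_advantages(2.0, 1.0)
        t_nw = replacement_time(p, crit)
        t_both = replacement_time(p)
        assert math.isfinite(t_nw)
        assert t_nw <= t_both  # NW alone falls below threshold no later


class TestSweeps:
    def test_single_neutral_cell(self, standard_params):
        res = sweep_advantages([1.0], [1.0], standard_params, t_max=1e3)
        assert res.times.shape == (1, 1)
        assert res.censored[0, 0]

    def test_monotone_in_both_advantages(self, standard_params):
        res = sweep_advantages(
            np.linspace(1.2, 2.0, 4), np.linspace(1.2, 2.0, 4), standard_params
        )
        assert np.isfinite(res.times).all()
        assert (np.diff(res.times, axis=0) <= 1e-3).all()
        assert (np.diff(res.times, axis=1) <= 1e-3).all()

    def test_invalid_cells_marked(self, standard_params):
        # a_V = 10 gives s_W = 1.0, s_W + s_M > 1 -> invalid
        res = sweep_advantages([1.5], [1.0, 10.0], standard_params, t_max=1e3)
        assert not res.invalid[0, 0]
        assert res.invalid[0, 1]
        assert np.isnan(res.times[0, 1])

    def test_influx_zero_matches_advantage_sweep(self, standard_params):
        adv = sweep_advantages([1.5], [1.0], standard_params)
        inf = sweep_influx([1.5], [0.0], standard_params)
        assert inf.times[0, 0] == pytest.approx(adv.times[0, 0], rel=1e-9)

    def test_influx_speeds_replacement(self, standard_params):
        res = sweep_influx([1.2], [0.0, 0.1], standard_params)
        assert res.times[0, 1] <= res.times[0, 0]

    def test_parameter_sweep_unknown_name(self, standard_params):
        with pytest.raises(ValueError, match="unknown sweepable"):
            sweep_parameter("rho", [1.0], [1.5], [1.0], standard_params)

    def test_parameter_sweep_standard_value_matches(self, standard_params):
        crit = ReplacementCriterion(mode="relative_frequency", threshold=0.01)
        [res] = sweep_parameter(
            "beta_W", [1.0], [1.5], [1.5], standard_params, criterion=crit
        )
        direct = sweep_advantages([1.5], [1.5], standard_params, criterion=crit)
        assert res.times[0, 0] == pytest.approx(direct.times[0, 0], rel=1e-9)

    def test_higher_baseline_conjugation_speeds_replacement(self, standard_params):
        res_lo, res_hi = sweep_parameter(
            "beta_W", [1.0, 2.0], [1.25, 1.75], [1.0], standard_params
        )
        assert (res_hi.times <= res_lo.times + 1e-3).all()

    def test_weaker_exclusion_speeds_replacement(self, standard_params):
        res_strong, res_weak = sweep_parameter(
            "k", [0.99, 0.9], [1.25, 1.75], [1.0], standard_params
        )
        assert (res_weak.times <= res_strong.times + 1e-3).all()

    def test_long_format_export(self, standard_params):
        res = sweep_advantages([1.2, 1.5], [1.0], standard_params, t_max=1e4)
        frame = res.to_frame()
        assert list(frame.columns) == ["a_H", "a_V", "time", "censored", "invalid"]
        assert len(frame) == 2


class TestEventOracle:
    def test_event_agrees_with_dense_scan(self, standard_params):
        """Event-detected crossing vs a 10x-finer brute-force scan."""
        p = standard_params.with_advantages(1.6, 1.0)
        t_event = replacement_time(p)
        t_eval = np.linspace(0.0, 1.1 * t_event, 20001)
        traj = simulate(p, standard_initial_state(p), 1.1 * t_event, t_eval=t_eval)
        wt = traj.y[1] + traj.y[3]
        first = np.flatnonzero(wt < 0.01)[0]
        dt = t_eval[1] - t_eval[0]
        assert abs(t_eval[first] - t_event) <= max(dt, 0.01 * t_event)


class TestSerialTransfer:
    def test_dilution_preserves_frequencies(self, standard_params):
        init = PopulationState(N0=0.5, NW=0.2, NM=0.2, NWM=0.0)
        res = simulate_serial_transfer(
            standard_params, init, n_days=2, dilution_factor=100.0
        )
        end = res.day_end_states[0].as_array()
        start_next = res.day_start_states[1].as_array()
        np.testing.assert_allclose(start_next, end / 100.0)
        # frequencies unchanged by the dilution event
        np.testing.assert_allclose(
            start_next / start_next.sum(), end / end.sum(), rtol=1e-12
        )

    def test_neutral_seeding_stays_symmetric(self, standard_params):
        init = PopulationState(N0=0.98, NW=0.01, NM=0.01, NWM=0.0)
        res = simulate_serial_transfer(standard_params, init, n_days=4)
        for state in res.day_end_states:
            assert state.NW == pytest.approx(state.NM, rel=1e-9, abs=1e-12)

    def test_mutant_overtakes_with_advantage_and_immigration(self, standard_params):
        p = standard_params.with_advantages(2.0, 1.0)
        init = PopulationState(N0=0.98, NW=0.01, NM=0.01, NWM=0.0)
        res = simulate_serial_transfer(p, init, n_days=8, immigrant_ratio=95.0)
        final = res.day_end_states[-1]
        mutant_carrying = final.NM + final.NWM
        wildtype_carrying = final.NW + final.NWM
        assert mutant_carrying > wildtype_carrying

    def test_invalid_dilution(self, standard_params):
        with pytest.raises(ValueError):
            simulate_serial_transfer(
                standard_params, PopulationState(N0=1.0), n_days=1, dilution_factor=1.0
            )


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    a_H=st.floats(1.0, 3.0),
    a_V=st.floats(1.0, 3.0),
    nwm=st.floats(1e-4, 0.05),
)
def test_states_stay_nonnegative_and_bounded(a_H, a_V, nwm):
    """Densities never go negative and, without influx, total density never
    exceeds max(initial total, K)."""
    p = ModelParams().with_advantages(a_H, a_V)
    if p.s_W + p.s_M > 1:
        return
    init = PopulationState(N0=0.0, NW=0.8, NM=0.0, NWM=nwm)
    traj = simulate(p, init, t_max=200.0, t_eval=np.linspace(0, 200, 21))
    assert traj.y.min() >= 0.0
    assert traj.y.sum(axis=0).max() <= max(init.total, p.K) + 1e-6


def test_scenario_roundtrip(tmp_path, standard_params):
    doc = """
params:
  beta_M: 1.5
  epsilon: 0.05
initial:
  N0: 0.1
  NW: 0.8
  NWM: 0.01
criterion:
  mode: relative_frequency
  threshold: 0.02
"""
    path = tmp_path / "scenario.yaml"
    path.write_text(doc)
    params, initial, criterion = load_scenario(path)
    assert params.beta_M == 1.5
    assert params.epsilon == 0.05
    assert params.rho == standard_params.rho  # defaults preserved
    assert initial.NW == 0.8
    assert criterion.mode == "relative_frequency"
    assert criterion.threshold == 0.02
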