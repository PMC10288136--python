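"""Thermoregulation solver: heat-balance bookkeeping, control signs,
integration behaviour and steady-state physiology."""

import dataclasses

import numpy as np
import pytest

from cabtherm import (
    BodyState,
    ControlSignals,
    IntegrationError,
    Microclimate,
    default_initial_state,
    energy_balance,
    mean_skin_temperature,
    passive_derivatives,
    simulate,
    steady_state,
)
from cabtherm.body_thermal import active_controls, respiratory_loss, skin_heat_loss
from cabtherm.physio import BLOOD, CORE, N_NODES, N_SEGMENTS, SKIN


def _no_source_params(params):
    """Parameter set with metabolism switched off."""
    return dataclasses.replace(params, met_basal=np.zeros(N_NODES))


def _uniform_state(t: float) -> BodyState:
    return BodyState(node_temperature=np.full(N_NODES, t))


@pytest.fixture()
def saturated_env():
    # saturated air suppresses the vapour-pressure gradient, so an
    # isothermal body/environment pair carries no flux at all
    return Microclimate.uniform(34.0, 0.1, rh=1.0)


class TestPassiveDerivatives:
    def test_isothermal_no_sources_gives_zero_derivatives(self, params, saturated_env):
        state = _uniform_state(34.0)
        d = passive_derivatives(state, saturated_env, _no_source_params(params),
                                ControlSignals.zero())
        assert np.all(d == 0.0)

    def test_basal_metabolism_heats_the_cores(self, params, saturated_env):
        state = _uniform_state(34.0)
        d = passive_derivatives(state, saturated_env, params, ControlSignals.zero())
        cores = d[CORE : 4 * N_SEGMENTS : 4]
        assert np.all(cores > 0)

    def test_capacity_weighted_sum_matches_flux_bookkeeping(self, params):
        # independent bookkeeping: production and loss re-derived from the
        # boundary terms only; internal exchanges must cancel exactly
        rng = np.random.default_rng(7)
        env = Microclimate(
            t_air=20 + 10 * rng.random(N_SEGMENTS),
            v_air=0.1 + rng.random(N_SEGMENTS),
            t_mrt=20 + 15 * rng.random(N_SEGMENTS),
            rh=0.3 + 0.4 * rng.random(N_SEGMENTS),
        )
        state = BodyState(node_temperature=33 + 4 * rng.random(N_NODES))
        controls = active_controls(state, params)
        d = passive_derivatives(state, env, params, controls)
        lhs = float(params.capacity @ d)

        production = float(params.met_basal.sum() + controls.shiver.sum())
        skin = state.node_temperature[SKIN : 4 * N_SEGMENTS : 4]
        loss = float(skin_heat_loss(skin, env, params, controls.sweat).sum())
        loss += respiratory_loss(env, production)
        assert lhs == pytest.approx(production - loss, rel=1e-9)

    def test_nonfinite_temperature_identifies_node(self, params, saturated_env):
        t = np.full(N_NODES, 34.0)
        t[13] = np.nan
        from cabtherm import NumericalError

        with pytest.raises(NumericalError, match="node 13"):
            passive_derivatives(BodyState(node_temperature=t), saturated_env,
                                params, ControlSignals.zero())


class TestActiveControls:
    def _setpoint_state(self, params) -> np.ndarray:
        t = np.empty(N_NODES)
        nodes = t[:BLOOD].reshape(N_SEGMENTS, 4)
        nodes[:, :] = params.core_setpoint
        nodes[:, SKIN] = params.skin_setpoint
        t[BLOOD] = params.core_setpoint
        return t

    def test_dead_band_at_setpoints(self, params):
        c = active_controls(BodyState(node_temperature=self._setpoint_state(params)), params)
        assert np.all(c.sweat == 0)
        assert np.all(c.shiver == 0)
        assert np.allclose(c.bf_mult, 1.0)

    def test_warm_core_sweats_without_shivering(self, params):
        t = self._setpoint_state(params)
        t[CORE : 4 * N_SEGMENTS : 4] += 1.0
        c = active_controls(BodyState(node_temperature=t), params)
        assert c.sweat.sum() > 0
        assert c.shiver.sum() == 0

    def test_cold_skin_shivers_and_constricts(self, params):
        t = self._setpoint_state(params)
        t[SKIN : 4 * N_SEGMENTS : 4] -= 2.0
        t[CORE : 4 * N_SEGMENTS : 4] -= 0.3
        c = active_controls(BodyState(node_temperature=t), params)
        assert c.shiver.sum() > 0
        assert np.all(c.bf_mult < 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_sweat_and_shiver_never_coexist(self, params, seed):
        rng = np.random.default_rng(seed)
        t = 30 + 10 * rng.random(N_NODES)
        c = active_controls(BodyState(node_temperature=t), params)
        assert c.sweat.sum() == 0 or c.shiver.sum() == 0
        assert np.all(c.bf_mult > 0)


class TestSimulate:
    def test_equilibrium_trajectory_is_constant(self, params, saturated_env):
        quiet = dataclasses.replace(
            _no_source_params(params),
            controls=dataclasses.replace(
                params.controls, sweat_gain_w=0.0, shiver_gain_w=0.0,
                dilation_gain=0.0, constriction_gain=0.0,
            ),
        )
        traj = simulate(saturated_env, quiet, duration=120, dt=2,
                        initial=_uniform_state(34.0))
        assert np.all(traj.temperatures == 34.0)

    def test_cold_step_skin_monotone_and_euler_sign(self, params):
        env = Microclimate.uniform(15.0, 0.2, rh=0.5)
        initial = default_initial_state(params)
        # oracle: the sign of a single explicit-Euler step per skin node
        d0 = passive_derivatives(initial, env, params,
                                 active_controls(initial, params))
        skin_d0 = d0[SKIN : 4 * N_SEGMENTS : 4]
        assert np.all(skin_d0 < 0)
        traj = simulate(env, params, duration=60, dt=2, initial=initial)
        skin = traj.temperatures[:, SKIN : 4 * N_SEGMENTS : 4]
        assert np.all(np.diff(skin, axis=0) <= 0)

    def test_rk4_step_halving_converged(self, params):
        env = Microclimate.uniform(28.0, 0.3, rh=0.5)
        t2 = simulate(env, params, duration=600, dt=2).final
        t1 = simulate(env, params, duration=600, dt=1).final
        assert np.max(np.abs(t2.skin - t1.skin)) < 0.01

    def test_determinism_bit_identical(self, params):
        env = Microclimate.uniform(28.0, 0.3, rh=0.5)
        a = simulate(env, params, duration=120, dt=2)
        b = simulate(env, params, duration=120, dt=2)
        assert np.array_equal(a.temperatures, b.temperatures)

    def test_band_violation_reports_node_and_time(self, params):
        t = np.full(N_NODES, 34.0)
        t[5] = 19.5
        env = Microclimate.uniform(25.0, 0.1, rh=0.5)
        with pytest.raises(IntegrationError, match="node 5"):
            simulate(env, params, duration=60, dt=2,
                     initial=BodyState(node_temperature=t))


class TestSteadyState:
    def test_thermoneutral_converges_with_physiological_mst(self, thermoneutral_state):
        mst = mean_skin_temperature(thermoneutral_state.skin)
        assert 33.0 <= mst <= 35.0

    def test_energy_closure_at_steady_state(self, params, thermoneutral_env,
                                            thermoneutral_state):
        controls = active_controls(thermoneutral_state, params)
        production, loss = energy_balance(
            thermoneutral_state, thermoneutral_env, params, controls)
        assert abs(production - loss) < 0.01 * production

    def test_hot_environment_warms_every_segment(self, params, thermoneutral_state):
        hot = Microclimate.uniform(35.0, 0.1, t_mrt=45.0, rh=0.5)
        state, _ = steady_state(hot, params)
        assert np.all(state.skin > thermoneutral_state.skin)

    def test_uniform_warming_never_cools_skin(self, params, thermoneutral_state):
        warmer = Microclimate.uniform(27.0, 0.1, t_mrt=27.0, rh=0.5)
        state, _ = steady_state(warmer, params)
        assert np.all(state.skin >= thermoneutral_state.skin)

    def test_infinite_tolerance_returns_initial(self, params):
        env = Microclimate.uniform(25.0, 0.1, rh=0.5)
        initial = default_initial_state(params)
        state, converged = steady_state(env, params, tol=np.inf)
        assert converged
        assert np.array_equal(state.node_temperature, initial.node_temperature)
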