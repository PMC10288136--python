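"""Multi-node thermoregulation solver (Stolwijk-type passive + active system).

The passive system is a 57-node heat-balance network: each of the 14
segments has core, muscle, fat and skin layers linked by conduction, all
layers exchange heat with a central blood pool by perfusion, and the skin
exchanges with the local microclimate by convection, linearised radiation
and evaporation through the clothing.  Respiratory loss is charged to the
chest core.  The active system converts skin/core deviations from their
set-points into sweating, shivering and vasomotor blood-flow changes.

Steady states are obtained by explicit fixed-step RK4 integration with
the active controls re-evaluated at every stage, run until the largest
node derivative falls below a tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import IntegrationError, NumericalError
from .physio import (
    BLOOD,
    CORE,
    FAT,
    MUSCLE,
    N_NODES,
    RHO_C_BLOOD,
    SKIN,
    TEMP_BAND,
    BodyState,
    ControlSignals,
    Microclimate,
    PhysioParams,
    default_initial_state,
    saturation_vapour_pressure,
)
from .segments import N_SEGMENTS, SEGMENTS, SegmentId

SIGMA = 5.670374419e-8
#: index of the chest core node (respiratory heat sink)
_CHEST_CORE = SEGMENTS.index(SegmentId.CHEST) * 4 + CORE
_HEAD_CORE = SEGMENTS.index(SegmentId.HEAD) * 4 + CORE
_CHEST = SEGMENTS.index(SegmentId.CHEST)

#: extra muscle perfusion per watt of shivering, L/h
_SHIVER_BF_PER_W = 1.0


def _check_state(state: BodyState) -> np.ndarray:
    t = state.node_temperature
    if not np.all(np.isfinite(t)):
        bad = int(np.argmin(np.isfinite(t)))
        raise NumericalError(f"non-finite temperature at node {bad}")
    return t


def skin_heat_loss(
    t_skin: np.ndarray,
    env: Microclimate,
    params: PhysioParams,
    sweat: np.ndarray,
) -> np.ndarray:
    """Per-segment heat loss (W) from the skin to the microclimate.

    Dry loss flows through the clothing resistance in series with the
    combined convective/radiative film; evaporative loss is passive
    diffusion (a fixed fraction of the evaporative capacity) plus sweat,
    capped at the capacity.
    """
    h_c = np.maximum(8.3 * env.v_air**0.6, 3.1)
    t_film = 0.5 * (t_skin + env.t_mrt) + 273.15
    h_r = 4.0 * params.emissivity * SIGMA * t_film**3
    # written so that t_op == t_air exactly when air and radiant agree
    t_op = env.t_air + h_r * (env.t_mrt - env.t_air) / (h_c + h_r)
    dry = params.area * (t_skin - t_op) / (params.clothing + 1.0 / (h_c + h_r))

    p_skin = saturation_vapour_pressure(t_skin)
    p_air = env.rh * saturation_vapour_pressure(env.t_air)
    r_e = params.clothing / (params.lewis_ratio * params.clothing_icl) + 1.0 / (
        params.lewis_ratio * h_c
    )
    e_max = np.maximum(params.area * (p_skin - p_air) / r_e, 0.0)
    evap = np.clip(params.skin_diffusion_fraction * e_max + sweat, 0.0, e_max)
    return dry + evap


def respiratory_loss(env: Microclimate, met_rate: float) -> float:
    """Respiratory heat loss (W), proportional to metabolic rate."""
    t_inh = env.t_air[_CHEST]
    p_inh = env.rh[_CHEST] * saturation_vapour_pressure(t_inh)
    return 0.0014 * met_rate * (34.0 - t_inh) + 0.0173 * met_rate * (5.87 - p_inh)


def _node_fluxes(
    state: BodyState,
    env: Microclimate,
    params: PhysioParams,
    controls: ControlSignals,
) -> tuple[np.ndarray, float, float]:
    """Net heat inflow (W) per node, total production, total loss."""
    t = _check_state(state)
    nodes = t[:BLOOD].reshape(N_SEGMENTS, 4)
    t_blood = t[BLOOD]

    met = params.met_basal[:BLOOD].reshape(N_SEGMENTS, 4).copy()
    met[:, MUSCLE] += controls.shiver

    bf = params.bf_basal[:BLOOD].reshape(N_SEGMENTS, 4).copy()
    bf[:, SKIN] *= controls.bf_mult
    bf[:, MUSCLE] += _SHIVER_BF_PER_W * controls.shiver
    k_blood = RHO_C_BLOOD * bf
    q_blood = k_blood * (t_blood - nodes)

    # inter-layer conduction, positive towards the outer layer
    k = params.conductance
    q_cm = k[:, 0] * (nodes[:, CORE] - nodes[:, MUSCLE])
    q_mf = k[:, 1] * (nodes[:, MUSCLE] - nodes[:, FAT])
    q_fs = k[:, 2] * (nodes[:, FAT] - nodes[:, SKIN])

    loss_skin = skin_heat_loss(nodes[:, SKIN], env, params, controls.sweat)
    met_rate = float(met.sum())
    q_resp = respiratory_loss(env, met_rate)

    q = np.empty(N_NODES)
    qn = q[:BLOOD].reshape(N_SEGMENTS, 4)
    qn[:, CORE] = met[:, CORE] + q_blood[:, CORE] - q_cm
    qn[:, MUSCLE] = met[:, MUSCLE] + q_blood[:, MUSCLE] + q_cm - q_mf
    qn[:, FAT] = met[:, FAT] + q_blood[:, FAT] + q_mf - q_fs
    qn[:, SKIN] = met[:, SKIN] + q_blood[:, SKIN] + q_fs - loss_skin
    q[_CHEST_CORE] -= q_resp
    q[BLOOD] = -q_blood.sum()  # the pool only redistributes heat

    total_loss = float(loss_skin.sum()) + q_resp
    return q, met_rate, total_loss


def passive_derivatives(
    state: BodyState,
    env: Microclimate,
    params: PhysioParams,
    controls: ControlSignals,
) -> np.ndarray:
    """Temperature derivative (degC/s) of every node.

    Energy is conserved exactly: the capacity-weighted sum of the
    derivatives equals total heat production minus total environmental
    loss, because perfusion and conduction terms cancel pairwise.
    """
    q, _, _ = _node_fluxes(state, env, params, controls)
    return q / params.capacity


def energy_balance(
    state: BodyState,
    env: Microclimate,
    params: PhysioParams,
    controls: ControlSignals,
) -> tuple[float, float]:
    """(total heat production, total environmental loss) in W."""
    _, production, loss = _node_fluxes(state, env, params, controls)
    return production, loss


def active_controls(state: BodyState, params: PhysioParams) -> ControlSignals:
    """Thermoregulatory effector outputs for the given state.

    Skin warm/cold receptor signals are the receptor-weighted positive and
    negative parts of the skin error; together with the head-core error
    they form a single drive signal whose positive part commands sweating
    and vasodilation and whose negative part commands shivering and
    vasoconstriction, so sweating and shivering are mutually exclusive.
    """
    _check_state(state)
    c = params.controls
    eps = state.skin - params.skin_setpoint
    wrm = float(params.receptor_w @ np.maximum(eps, 0.0))
    cld = float(params.receptor_w @ np.maximum(-eps, 0.0))
    eps_core = float(state.node_temperature[_HEAD_CORE]) - params.core_setpoint

    sig = c.sig_core_gain * eps_core + c.sig_skin_gain * (wrm - cld)
    sweat_total = min(c.sweat_gain_w * max(sig, 0.0), c.sweat_max_w)
    shiver_total = min(c.shiver_gain_w * max(-sig, 0.0), c.shiver_max_w)

    sig_v = c.vaso_core_gain * eps_core + c.vaso_skin_gain * (wrm - cld)
    mult = (1.0 + c.dilation_gain * max(sig_v, 0.0)) / (
        1.0 + c.constriction_gain * max(-sig_v, 0.0)
    )
    mult = float(np.clip(mult, c.bf_mult_min, c.bf_mult_max))

    return ControlSignals(
        sweat=sweat_total * params.sweat_w,
        shiver=shiver_total * params.shiver_w,
        bf_mult=np.full(N_SEGMENTS, mult),
    )


def _rhs(t_vec: np.ndarray, env: Microclimate, params: PhysioParams) -> np.ndarray:
    state = BodyState(node_temperature=t_vec)
    controls = active_controls(state, params)
    return passive_derivatives(state, env, params, controls)


@dataclass(frozen=True)
class Trajectory:
    """Time-stamped temperature history of a simulation."""

    times: np.ndarray          # (n,) s
    temperatures: np.ndarray   # (n, 57) degC

    def state(self, i: int) -> BodyState:
        return BodyState(node_temperature=self.temperatures[i], time=float(self.times[i]))

    @property
    def final(self) -> BodyState:
        return self.state(len(self.times) - 1)


def _band_check(t_vec: np.ndarray, time: float) -> None:
    lo, hi = TEMP_BAND
    if np.any(t_vec < lo) or np.any(t_vec > hi):
        bad = int(np.argmax((t_vec < lo) | (t_vec > hi)))
        raise IntegrationError(
            f"node {bad} left the physiological band "
            f"[{lo}, {hi}] degC at t={time:.1f} s (T={t_vec[bad]:.2f})"
        )


def simulate(
    env: Microclimate,
    params: PhysioParams,
    duration: float,
    dt: float = 2.0,
    initial: BodyState | None = None,
) -> Trajectory:
    """Fixed-step RK4 integration of the coupled passive/active system.

    The active controls are re-evaluated at every RK4 stage, so the
    trajectory is a deterministic function of the inputs and the step.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration < dt:
        raise ValueError("duration must be at least one step")
    state = default_initial_state(params) if initial is None else initial
    n_steps = int(round(duration / dt))
    t_vec = state.node_temperature.copy()
    times = state.time + dt * np.arange(n_steps + 1)
    temps = np.empty((n_steps + 1, N_NODES))
    temps[0] = t_vec
    _band_check(t_vec, float(times[0]))
    for i in range(n_steps):
        k1 = _rhs(t_vec, env, params)
        k2 = _rhs(t_vec + 0.5 * dt * k1, env, params)
        k3 = _rhs(t_vec + 0.5 * dt * k2, env, params)
        k4 = _rhs(t_vec + dt * k3, env, params)
        t_vec = t_vec + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        _band_check(t_vec, float(times[i + 1]))
        temps[i + 1] = t_vec
    return Trajectory(times=times, temperatures=temps)


def steady_state(
    env: Microclimate,
    params: PhysioParams,
    tol: float = 0.001,
    max_time: float = 7200.0,
    dt: float = 2.0,
    initial: BodyState | None = None,
) -> tuple[BodyState, bool]:
    """Integrate towards equilibrium.

    ``tol`` is the convergence threshold on the largest node derivative in
    degC/min.  Returns the final state and a flag reporting whether the
    tolerance was met before ``max_time`` simulated seconds.
    """
    if not tol > 0:
        raise ValueError("tol must be positive")
    state = default_initial_state(params) if initial is None else initial
    if np.isinf(tol):
        return state, True
    chunk = 120.0
    elapsed = 0.0
    while elapsed < max_time:
        span = min(chunk, max_time - elapsed)
        if span < dt:
            break
        traj = simulate(env, params, duration=span, dt=dt, initial=state)
        state = traj.final
        elapsed += span
        deriv = _rhs(state.node_temperature, env, params)
        if np.max(np.abs(deriv)) * 60.0 < tol:
            return state, True
    deriv = _rhs(state.node_temperature, env, params)
    return state, bool(np.max(np.abs(deriv)) * 60.0 < tol)
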