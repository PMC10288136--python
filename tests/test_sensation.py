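"""Sensation model: mean skin temperature, the local-sensation sigmoid,
the deviation-weighted overall vote, and the full comfort evaluation."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cabtherm import (
    ConfigurationError,
    Microclimate,
    SegmentId,
    evaluate_comfort,
    local_sensation,
    mean_skin_temperature,
    overall_sensation,
)
from cabtherm.segments import MIRROR, N_SEGMENTS, SEGMENT_INDEX, SEGMENTS, SEVEN_SITES
from cabtherm.sensation import local_sensations_steady


class TestMeanSkinTemperature:
    def test_weights_sum_to_one_exactly(self):
        assert sum(w for _, w in SEVEN_SITES) == 1.0

    def test_uniform_temperature_is_identity(self):
        assert mean_skin_temperature(np.full(N_SEGMENTS, 34.0)) == pytest.approx(34.0)

    def test_reference_initial_temperatures(self):
        # hand evaluation of the weighted sum over the tabulated sites:
        # 0.07*36 + 0.35*35 + 0.14*35 + 0.05*35 + 0.19*35 + 0.13*34 + 0.07*36
        sites = {
            SegmentId.HEAD: 36.0,
            SegmentId.CHEST: 35.0,
            SegmentId.L_LOWER_ARM: 35.0,
            SegmentId.L_HAND: 35.0,
            SegmentId.L_UPPER_LEG: 35.0,
            SegmentId.L_LOWER_LEG: 34.0,
            SegmentId.L_FOOT: 36.0,
        }
        assert mean_skin_temperature(sites) == pytest.approx(35.01)

    @given(shift=st.floats(-5, 5))
    @settings(max_examples=25, deadline=None)
    def test_translation_equivariance(self, shift):
        base = np.linspace(32, 36, N_SEGMENTS)
        assert mean_skin_temperature(base + shift) == pytest.approx(
            mean_skin_temperature(base) + shift, abs=1e-9
        )

    def test_missing_site_raises(self):
        with pytest.raises(ConfigurationError, match="missing"):
            mean_skin_temperature({SegmentId.HEAD: 36.0})


def _toy_coeffs(coeffs, **overrides):
    return dataclasses.replace(coeffs, **overrides)


class TestLocalSensation:
    def test_zero_at_setpoint(self, coeffs):
        i = SEGMENT_INDEX[SegmentId.CHEST]
        s = local_sensation(
            coeffs.skin_setpoint[i], coeffs.mean_setpoint, 0.0, 0.0,
            coeffs, SegmentId.CHEST,
        )
        assert s == pytest.approx(0.0)

    def test_limits_saturate_the_scale(self, coeffs):
        i = SEGMENT_INDEX[SegmentId.HEAD]
        hot = local_sensation(coeffs.skin_setpoint[i] + 40, coeffs.mean_setpoint,
                              0.0, 0.0, coeffs, SegmentId.HEAD)
        cold = local_sensation(coeffs.skin_setpoint[i] - 40, coeffs.mean_setpoint,
                               0.0, 0.0, coeffs, SegmentId.HEAD)
        assert hot == pytest.approx(4.0, abs=1e-6)
        assert cold == pytest.approx(-4.0, abs=1e-6)

    def test_hand_evaluated_sigmoid_value(self, coeffs):
        # C1=1, K1=0.1, +1 degC local offset with the mean at its
        # set-point: argument 1.1, so 4*(2/(1+e^-1.1)-1) = 2.0020
        toy = _toy_coeffs(
            coeffs,
            c1_warm=np.ones(N_SEGMENTS),
            k1=0.1,
            skin_setpoint=np.full(N_SEGMENTS, 34.0),
            mean_setpoint=34.0,
        )
        s = local_sensation(35.0, 34.0, 0.0, 0.0, toy, SegmentId.CHEST)
        assert s == pytest.approx(4.0 * (2.0 / (1.0 + np.exp(-1.1)) - 1.0), abs=1e-9)
        assert s == pytest.approx(2.002, abs=5e-4)

    @given(t=st.floats(28, 42), dt=st.floats(0.05, 1.0))
    @settings(max_examples=30, deadline=None)
    def test_static_part_strictly_increasing_in_skin(self, coeffs, t, dt):
        lo = local_sensation(t, coeffs.mean_setpoint, 0.0, 0.0, coeffs, SegmentId.CHEST)
        hi = local_sensation(t + dt, coeffs.mean_setpoint, 0.0, 0.0, coeffs,
                             SegmentId.CHEST)
        if abs(lo) < 4 and abs(hi) < 4:  # strict away from the clamp
            assert hi > lo
        else:
            assert hi >= lo

    def test_always_clamped_to_scale(self, coeffs):
        rng = np.random.default_rng(1)
        skins = 20 + 25 * rng.random((20, N_SEGMENTS))
        for row in skins:
            s = local_sensations_steady(row, coeffs)
            assert np.all(s >= -4.0) and np.all(s <= 4.0)


class TestOverallSensation:
    def test_uniform_locals_return_that_value(self, coeffs):
        assert overall_sensation(np.full(N_SEGMENTS, 1.7), coeffs) == pytest.approx(1.7)

    def test_hand_evaluated_deviation_weighting(self, coeffs):
        # locals: one part at +2, the rest at 0; slopes 1 (cold) / 2 (warm).
        # S_m = 1/7; w_i = a_i (S_i - S_m) gives sum(w) = 13/7 and
        # sum(w S) = 52/7, so the raw vote 4.0 sits at the clamp.
        toy = _toy_coeffs(
            coeffs,
            a_cold=np.ones(N_SEGMENTS),
            a_warm=np.full(N_SEGMENTS, 2.0),
        )
        locals_ = np.zeros(N_SEGMENTS)
        locals_[0] = 2.0
        assert overall_sensation(locals_, toy) == pytest.approx(4.0)

    def test_equal_slopes_fall_back_to_the_mean(self, coeffs):
        toy = _toy_coeffs(
            coeffs,
            a_cold=np.full(N_SEGMENTS, 0.6),
            a_warm=np.full(N_SEGMENTS, 0.6),
        )
        locals_ = np.linspace(-1.0, 2.0, N_SEGMENTS)
        assert overall_sensation(locals_, toy) == pytest.approx(locals_.mean())

    def test_clamped_to_scale_for_any_input(self, coeffs):
        rng = np.random.default_rng(3)
        for _ in range(30):
            locals_ = -4 + 8 * rng.random(N_SEGMENTS)
            assert abs(overall_sensation(locals_, coeffs)) <= 4.0


class TestEvaluateComfort:
    def test_thermoneutral_near_neutral_vote(self, params, coeffs, thermoneutral_env):
        r = evaluate_comfort(thermoneutral_env, params, coeffs)
        assert r.converged
        assert abs(r.otsv) <= 0.5

    def test_deterministic(self, params, coeffs):
        env = Microclimate.uniform(27.0, 0.2, rh=0.5)
        a = evaluate_comfort(env, params, coeffs)
        b = evaluate_comfort(env, params, coeffs)
        assert np.array_equal(a.ltsv, b.ltsv)
        assert a.otsv == b.otsv and a.mst == b.mst

    def test_warmer_environment_never_reads_cooler(self, params, coeffs):
        cool = Microclimate.uniform(24.0, 0.2, rh=0.5)
        warm = Microclimate.uniform(27.0, 0.2, t_mrt=29.0, rh=0.5)
        assert (evaluate_comfort(warm, params, coeffs).otsv
                >= evaluate_comfort(cool, params, coeffs).otsv)

    def test_left_right_mirror_symmetry(self, params, coeffs):
        # asymmetric jet on the left side only
        t_air = np.full(N_SEGMENTS, 27.0)
        v = np.full(N_SEGMENTS, 0.1)
        for seg in (SegmentId.L_HAND, SegmentId.L_LOWER_ARM, SegmentId.L_UPPER_ARM):
            i = SEGMENT_INDEX[seg]
            t_air[i] = 20.0
            v[i] = 1.0
        env = Microclimate(t_air=t_air, v_air=v,
                           t_mrt=np.full(N_SEGMENTS, 28.0),
                           rh=np.full(N_SEGMENTS, 0.5))
        perm = np.array([SEGMENT_INDEX[MIRROR[s]] for s in SEGMENTS])
        r = evaluate_comfort(env, params, coeffs)
        r_mirror = evaluate_comfort(env.mirrored(), params, coeffs)
        assert np.allclose(r_mirror.ltsv, r.ltsv[perm], atol=1e-9)
        assert r_mirror.otsv == pytest.approx(r.otsv, abs=1e-9)

    def test_serializes_to_per_segment_table(self, params, coeffs, thermoneutral_env):
        frame = evaluate_comfort(thermoneutral_env, params, coeffs).to_frame()
        assert len(frame) == N_SEGMENTS + 1
        assert frame["part"].iloc[-1] == "overall"
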