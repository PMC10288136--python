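"""Local and overall thermal sensation on the 9-point ASHRAE scale.

Local sensation of a body part is a sigmoid of the deviation of its skin
temperature from a set-point, coupled to the deviation of the mean skin
temperature, plus dynamic terms in the skin- and core-temperature
derivatives:

    S_i = 4 * (2 / (1 + exp(-C1*(T_sk,i - T_set,i)
                            - K1*[(T_sk,i - Tbar_sk) - (T_set,i - Tbar_set)])) - 1)
          + C2_i * dT_sk,i/dt + C3_i * dT_core/dt

Overall sensation is a weighted average of the locals with weights
w_i = a_i * (S_i - S_m), where S_m is the arithmetic mean of the locals,
so parts deviating from the prevailing sensation dominate.  Every vote
is clamped to [-4, +4].  The mean skin temperature is the seven-site
Hardy/DuBois weighted average.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .physio import BodyState, Microclimate, PhysioParams
from .segments import N_SEGMENTS, SEGMENTS, SEVEN_SITES, SegmentId

SCALE = (-4.0, 4.0)


@dataclass(frozen=True)
class SensationCoefficients:
    """Per-part sensation coefficients (arrays in canonical segment order)."""

    c1_cold: np.ndarray
    c1_warm: np.ndarray
    k1: float
    c2_cold: np.ndarray
    c2_warm: np.ndarray
    c3: np.ndarray
    a_cold: np.ndarray
    a_warm: np.ndarray
    skin_setpoint: np.ndarray
    mean_setpoint: float


def load_sensation_coeffs(
    path: str | Path | None = None,
    skin_setpoint: np.ndarray | None = None,
) -> SensationCoefficients:
    """Load the coefficient table (packaged default or a YAML file).

    Set-points default to the tabulated reference skin temperatures; the
    seven-site mean set-point is derived from them.
    """
    if path is None:
        text = resources.files("cabtherm.data").joinpath("sensation.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    parts = raw["parts"]
    missing = [s.value for s in SEGMENTS if s.value not in parts]
    if missing:
        raise ConfigurationError(f"sensation file missing parts: {missing}")

    def col(key: str) -> np.ndarray:
        return np.array([parts[s.value][key] for s in SEGMENTS], dtype=float)

    if skin_setpoint is None:
        from .physio import INITIAL_SKIN

        skin_setpoint = np.array([INITIAL_SKIN[s] for s in SEGMENTS])
    skin_setpoint = np.asarray(skin_setpoint, dtype=float)
    c = SensationCoefficients(
        c1_cold=col("c1_cold"),
        c1_warm=col("c1_warm"),
        k1=float(raw["k1"]),
        c2_cold=col("c2_cold"),
        c2_warm=col("c2_warm"),
        c3=col("c3"),
        a_cold=col("a_cold"),
        a_warm=col("a_warm"),
        skin_setpoint=skin_setpoint,
        mean_setpoint=mean_skin_temperature(skin_setpoint),
    )
    if np.any(c.c1_cold <= 0) or np.any(c.c1_warm <= 0):
        raise ConfigurationError("C1 must be positive for every part")
    if c.k1 < 0 or np.any(c.a_cold < 0) or np.any(c.a_warm < 0):
        raise ConfigurationError("K1 and the a_i weights must be non-negative")
    return c


def mean_skin_temperature(t_skin: Mapping[SegmentId, float] | np.ndarray) -> float:
    """Seven-site Hardy/DuBois mean skin temperature (degC).

    Accepts either the full 14-entry skin vector in canonical order or a
    mapping that contains at least the seven measurement sites (head,
    chest, left lower arm, left hand, left upper leg, left lower leg,
    left foot); the weights sum to 1 exactly.
    """
    if isinstance(t_skin, Mapping):
        missing = [s.value for s, _ in SEVEN_SITES if s not in t_skin]
        if missing:
            raise ConfigurationError(f"mean skin temperature missing sites: {missing}")
        return float(sum(w * float(t_skin[s]) for s, w in SEVEN_SITES))
    t = np.asarray(t_skin, dtype=float)
    if t.shape != (N_SEGMENTS,):
        raise ConfigurationError(
            f"expected a mapping of the 7 sites or a length-{N_SEGMENTS} skin vector"
        )
    from .segments import SEGMENT_INDEX

    return float(sum(w * t[SEGMENT_INDEX[s]] for s, w in SEVEN_SITES))


def symmetric_mean_skin(t_skin: np.ndarray) -> float:
    """Seven-site mean with the paired sites averaged left/right.

    Used as the whole-body coupling temperature of the sensation model so
    that mirrored environments produce mirrored votes; it coincides with
    the plain seven-site mean whenever the body is left/right symmetric.
    """
    from .segments import MIRROR, SEGMENT_INDEX

    t = np.asarray(t_skin, dtype=float)
    return float(sum(
        w * 0.5 * (t[SEGMENT_INDEX[s]] + t[SEGMENT_INDEX[MIRROR[s]]])
        for s, w in SEVEN_SITES
    ))


def _static_term(
    t_skin: np.ndarray,
    t_skin_mean: float,
    coeffs: SensationCoefficients,
) -> np.ndarray:
    delta = t_skin - coeffs.skin_setpoint
    c1 = np.where(delta < 0.0, coeffs.c1_cold, coeffs.c1_warm)
    coupling = (t_skin - t_skin_mean) - (coeffs.skin_setpoint - coeffs.mean_setpoint)
    arg = c1 * delta + coeffs.k1 * coupling
    return 4.0 * (2.0 / (1.0 + np.exp(-arg)) - 1.0)


def local_sensation(
    t_skin_i: float,
    t_skin_mean: float,
    dt_skin_dt: float,
    dt_core_dt: float,
    coeffs: SensationCoefficients,
    part: SegmentId,
) -> float:
    """Local thermal sensation vote of one body part, clamped to [-4, 4]."""
    i = SEGMENTS.index(part)
    delta = t_skin_i - coeffs.skin_setpoint[i]
    c1 = coeffs.c1_cold[i] if delta < 0 else coeffs.c1_warm[i]
    coupling = (t_skin_i - t_skin_mean) - (coeffs.skin_setpoint[i] - coeffs.mean_setpoint)
    arg = c1 * delta + coeffs.k1 * coupling
    static = 4.0 * (2.0 / (1.0 + np.exp(-arg)) - 1.0)
    c2 = coeffs.c2_cold[i] if dt_skin_dt < 0 else coeffs.c2_warm[i]
    s = static + c2 * dt_skin_dt + coeffs.c3[i] * dt_core_dt
    return float(np.clip(s, *SCALE))


def local_sensations_steady(
    t_skin: np.ndarray, coeffs: SensationCoefficients
) -> np.ndarray:
    """All 14 steady-state local votes (dynamic terms zero) at once."""
    t = np.asarray(t_skin, dtype=float)
    return np.clip(_static_term(t, symmetric_mean_skin(t), coeffs), *SCALE)


def overall_sensation(locals_: np.ndarray, coeffs: SensationCoefficients) -> float:
    """Overall vote from the 14 local votes.

    Weights w_i = a_i * (S_i - S_m) emphasise parts that deviate from the
    mean local sensation S_m, with cold/warm slopes a_i chosen by the
    sign of the deviation.  When the weights cancel (uniform sensation,
    or symmetric deviations under equal slopes) the mean is returned.
    """
    s = np.asarray(locals_, dtype=float)
    if s.shape != (N_SEGMENTS,):
        raise ConfigurationError(f"need all {N_SEGMENTS} local votes, got {s.shape}")
    s_m = float(s.mean())
    dev = s - s_m
    a = np.where(dev < 0.0, coeffs.a_cold, coeffs.a_warm)
    w = a * dev
    w_sum = float(w.sum())
    if abs(w_sum) < 1e-9:
        return float(np.clip(s_m, *SCALE))
    return float(np.clip(float(w @ s) / w_sum, *SCALE))


@dataclass(frozen=True)
class ComfortResult:
    """Steady-state comfort evaluation of one operating condition."""

    skin_temperature: np.ndarray   # (14,) degC
    mst: float                     # degC
    ltsv: np.ndarray               # (14,) sensation scale
    otsv: float                    # sensation scale
    converged: bool

    def to_frame(self) -> pd.DataFrame:
        """One row per segment plus an overall summary row."""
        rows = pd.DataFrame(
            {
                "part": [s.value for s in SEGMENTS],
                "skin_temperature_c": self.skin_temperature,
                "ltsv": self.ltsv,
            }
        )
        summary = pd.DataFrame(
            {
                "part": ["overall"],
                "skin_temperature_c": [self.mst],
                "ltsv": [self.otsv],
            }
        )
        return pd.concat([rows, summary], ignore_index=True)


def evaluate_comfort(
    env: Microclimate,
    params: PhysioParams,
    coeffs: SensationCoefficients,
    tol: float = 0.001,
    max_time: float = 7200.0,
    dt: float = 2.0,
    initial: BodyState | None = None,
) -> ComfortResult:
    """Full steady-state evaluation: physiology solve, MST, LTSV, OTSV.

    The dynamic sensation terms vanish at steady state (the temperature
    derivatives are below the convergence tolerance), so only the static
    sigmoid contributes.
    """
    from .body_thermal import steady_state

    state, converged = steady_state(
        env, params, tol=tol, max_time=max_time, dt=dt, initial=initial
    )
    skin = state.skin.copy()
    ltsv = local_sensations_steady(skin, coeffs)
    return ComfortResult(
        skin_temperature=skin,
        mst=mean_skin_temperature(skin),
        ltsv=ltsv,
        otsv=overall_sensation(ltsv, coeffs),
        converged=converged,
    )
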