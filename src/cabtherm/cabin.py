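"""Deterministic lumped-parameter cab microclimate.

Maps the five HVAC/solar design factors (supply air temperature and
volume, supply angle, solar radiation, solar altitude) to the
per-segment environment the physiology model consumes.  A steady-state
mixed-air energy balance gives the bulk cab temperature; fixed
jet-exposure and solar-view tables then distribute air temperature, air
speed and mean radiant temperature over the body segments.  The module
is smooth in the continuous factors and contains no randomness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, RangeError
from .physio import Microclimate
from .segments import N_SEGMENTS, SEGMENTS

#: factor box: supply temperature degC, supply volume m3/h, supply angle
#: degrees (two levels), solar radiation W/m2, solar altitude rad
BOUNDS: dict[str, tuple[float, float]] = {
    "t_supply": (10.0, 20.0),
    "q_supply": (500.0, 800.0),
    "solar": (900.0, 1300.0),
    "altitude": (0.8, 1.4),
}
ANGLE_LEVELS: tuple[float, ...] = (45.0, 90.0)
CONTINUOUS_FACTORS = ("t_supply", "q_supply", "solar", "altitude")
FACTORS = ("t_supply", "q_supply", "angle", "solar", "altitude")


@dataclass(frozen=True)
class DesignPoint:
    """One HVAC + solar operating condition."""

    t_supply: float   # degC
    q_supply: float   # m3/h
    angle: float      # degrees, 45 or 90
    solar: float      # W/m2
    altitude: float   # rad

    def validate(self) -> "DesignPoint":
        for name, (lo, hi) in BOUNDS.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise RangeError(f"{name}={v} outside [{lo}, {hi}]")
        if self.angle not in ANGLE_LEVELS:
            raise RangeError(f"angle={self.angle} not in levels {ANGLE_LEVELS}")
        return self

    def as_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in FACTORS}


@dataclass(frozen=True)
class CabinParams:
    """Constants of the lumped cab model (see ``data/cabin.yaml``)."""

    outdoor_temp: float
    outdoor_rh: float
    indoor_rh: float
    u_body: float
    u_window: float
    area_envelope: float
    area_window: float
    transmissivity: float
    windshield_tilt: float
    internal_gain: float
    vent_area: float
    air_density: float
    air_cp: float
    min_air_speed: float
    h_rad_norm: float
    jet_exposure: dict[float, np.ndarray]   # angle level -> (14,)
    solar_view: np.ndarray                  # (14,)
    floor_heat: np.ndarray                  # (14,)


def load_cabin_params(path: str | Path | None = None) -> CabinParams:
    if path is None:
        text = resources.files("cabtherm.data").joinpath("cabin.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)

    def seg_vector(mapping: dict, default: float = 0.0) -> np.ndarray:
        return np.array([float(mapping.get(s.value, default)) for s in SEGMENTS])

    jet = {}
    for key, table in raw["jet_exposure"].items():
        missing = [s.value for s in SEGMENTS if s.value not in table]
        if missing:
            raise ConfigurationError(f"jet_exposure[{key}] missing segments: {missing}")
        jet[float(key)] = seg_vector(table)
    p = CabinParams(
        outdoor_temp=raw["outdoor_temp_c"],
        outdoor_rh=raw["outdoor_rh"],
        indoor_rh=raw["indoor_rh"],
        u_body=raw["u_body_w_per_m2k"],
        u_window=raw["u_window_w_per_m2k"],
        area_envelope=raw["area_envelope_m2"],
        area_window=raw["area_window_m2"],
        transmissivity=raw["transmissivity"],
        windshield_tilt=raw["windshield_tilt_rad"],
        internal_gain=raw["internal_gain_w"],
        vent_area=raw["vent_area_m2"],
        air_density=raw["air_density_kg_per_m3"],
        air_cp=raw["air_cp_j_per_kgk"],
        min_air_speed=raw["min_air_speed_m_per_s"],
        h_rad_norm=raw["h_rad_norm_w_per_m2k"],
        jet_exposure=jet,
        solar_view=seg_vector(raw["solar_view"]),
        floor_heat=seg_vector(raw.get("floor_heat", {})),
    )
    if p.area_envelope <= 0 or p.area_window <= 0 or p.vent_area <= 0:
        raise ConfigurationError("areas must be positive")
    if p.transmissivity <= 0:
        raise ConfigurationError("transmissivity must be positive")
    if any(np.any(v < 0) for v in p.jet_exposure.values()) or np.any(p.solar_view < 0):
        raise ConfigurationError("jet exposure and solar view weights must be >= 0")
    return p


def _solar_gain(point: DesignPoint, params: CabinParams) -> float:
    """Transmitted solar load through the windshield, W."""
    incidence = math.cos(point.altitude - params.windshield_tilt)
    return params.transmissivity * params.area_window * point.solar * max(incidence, 0.0)


def cabin_bulk_temperature(point: DesignPoint, params: CabinParams) -> float:
    """Steady-state mixed-air cab temperature (degC), in closed form.

    Supply-air enthalpy removal balances envelope/window transmission,
    transmitted solar and internal equipment gains:
    m_dot*cp*(T_cab - T_sup) = UA*(T_out - T_cab) + Q_solar + Q_int.
    """
    point.validate()
    m_cp = params.air_density * point.q_supply / 3600.0 * params.air_cp
    ua = params.u_body * params.area_envelope + params.u_window * params.area_window
    load = _solar_gain(point, params) + params.internal_gain
    return (m_cp * point.t_supply + ua * params.outdoor_temp + load) / (m_cp + ua)


def microclimate(point: DesignPoint, params: CabinParams) -> Microclimate:
    """Per-segment air temperature, air speed and mean radiant temperature.

    Segments in the supply jet (head, hands, chest, strongest at a
    45-degree supply angle) see air pulled towards the supply temperature
    and higher speeds; the windshield's transmitted solar load raises the
    mean radiant temperature of the upper body, while a warm-floor term
    keeps the calves on the warm side.
    """
    point.validate()
    t_cab = cabin_bulk_temperature(point, params)
    if point.angle not in params.jet_exposure:
        raise ConfigurationError(f"no jet-exposure table for angle {point.angle}")
    d = params.jet_exposure[point.angle]

    t_air = t_cab - d * (t_cab - point.t_supply)
    bulk_speed = point.q_supply / (3600.0 * params.vent_area)
    v_air = np.maximum(bulk_speed * d, params.min_air_speed)
    solar_flux = _solar_gain(point, params) / params.area_window  # W/m2 transmitted
    t_mrt = t_cab + (params.solar_view + params.floor_heat) * solar_flux / params.h_rad_norm
    rh = np.full(N_SEGMENTS, params.indoor_rh)
    return Microclimate(t_air=t_air, v_air=v_air, t_mrt=t_mrt, rh=rh)


def microclimate_frame(point: DesignPoint, params: CabinParams) -> pd.DataFrame:
    """Microclimate as a segment x {t_air, v_air, t_mrt, rh} table."""
    env = microclimate(point, params)
    return pd.DataFrame(
        {
            "part": [s.value for s in SEGMENTS],
            "t_air_c": env.t_air,
            "v_air_m_per_s": env.v_air,
            "t_mrt_c": env.t_mrt,
            "rh": env.rh,
        }
    )
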