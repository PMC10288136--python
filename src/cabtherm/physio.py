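"""Physiological state, parameters and the segment microclimate container.

The thermoregulation solver works on a 57-node state vector: 14 segments
x 4 tissue layers (core, muscle, fat, skin) plus a central blood pool.
Node ``i*4 + l`` is layer ``l`` of segment ``i``; node 56 is blood.
Parameters are loaded from the packaged ``data/physiology.yaml`` file,
which stores per-segment primitives; node-level heat capacities, basal
metabolic rates, conductances and perfusions are derived here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError
from .segments import N_SEGMENTS, SEGMENTS, SegmentId

# layer indices
CORE, MUSCLE, FAT, SKIN = 0, 1, 2, 3
LAYERS = ("core", "muscle", "fat", "skin")
N_NODES = N_SEGMENTS * 4 + 1
BLOOD = N_NODES - 1

#: physiological band outside which the solver aborts, degC
TEMP_BAND = (20.0, 45.0)

#: volumetric heat equivalent of blood flow, W/K per L/h
RHO_C_BLOOD = 1.067


def node_index(segment: SegmentId, layer: int) -> int:
    """Flat node index of ``layer`` (0..3) of ``segment``."""
    return SEGMENTS.index(segment) * 4 + layer


def saturation_vapour_pressure(t_c: np.ndarray | float) -> np.ndarray | float:
    """Saturation water-vapour pressure in kPa (Magnus-Tetens)."""
    t = np.asarray(t_c, dtype=float)
    out = 0.61078 * np.exp(17.27 * t / (t + 237.3))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class Microclimate:
    """Per-segment thermal environment seen by the body.

    All arrays are indexed in canonical segment order and have length 14:
    air temperature (degC), air speed (m/s), mean radiant temperature
    (degC) and relative humidity (fraction 0..1).
    """

    t_air: np.ndarray
    v_air: np.ndarray
    t_mrt: np.ndarray
    rh: np.ndarray

    def __post_init__(self) -> None:
        for name in ("t_air", "v_air", "t_mrt", "rh"):
            a = np.asarray(getattr(self, name), dtype=float)
            if a.shape != (N_SEGMENTS,):
                raise ConfigurationError(
                    f"Microclimate.{name} must have one entry per segment "
                    f"(got shape {a.shape})"
                )
            object.__setattr__(self, name, a)

    @classmethod
    def uniform(
        cls, t_air: float, v_air: float = 0.1, t_mrt: float | None = None, rh: float = 0.5
    ) -> "Microclimate":
        """Spatially uniform environment (thermal-chamber style)."""
        ones = np.ones(N_SEGMENTS)
        return cls(
            t_air=t_air * ones,
            v_air=v_air * ones,
            t_mrt=(t_air if t_mrt is None else t_mrt) * ones,
            rh=rh * ones,
        )

    @classmethod
    def from_mapping(cls, per_segment: dict[SegmentId, tuple[float, float, float, float]]) -> "Microclimate":
        """Build from a mapping segment -> (t_air, v_air, t_mrt, rh)."""
        missing = [s.value for s in SEGMENTS if s not in per_segment]
        if missing:
            raise ConfigurationError(f"microclimate missing segments: {missing}")
        rows = np.array([per_segment[s] for s in SEGMENTS], dtype=float)
        return cls(t_air=rows[:, 0], v_air=rows[:, 1], t_mrt=rows[:, 2], rh=rows[:, 3])

    def mirrored(self) -> "Microclimate":
        """Left/right mirrored environment."""
        from .segments import MIRROR, SEGMENT_INDEX

        perm = np.array([SEGMENT_INDEX[MIRROR[s]] for s in SEGMENTS])
        return Microclimate(
            t_air=self.t_air[perm], v_air=self.v_air[perm],
            t_mrt=self.t_mrt[perm], rh=self.rh[perm],
        )


@dataclass(frozen=True)
class BodyState:
    """Temperatures (degC) of the 57 thermal nodes at a given time (s)."""

    node_temperature: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.node_temperature, dtype=float)
        if t.shape != (N_NODES,):
            raise ConfigurationError(f"state must have {N_NODES} nodes, got {t.shape}")
        object.__setattr__(self, "node_temperature", t)

    @property
    def skin(self) -> np.ndarray:
        """Skin-layer temperatures, one per segment (length 14)."""
        return self.node_temperature[SKIN : 4 * N_SEGMENTS : 4]

    @property
    def core(self) -> np.ndarray:
        """Core-layer temperatures, one per segment."""
        return self.node_temperature[CORE : 4 * N_SEGMENTS : 4]

    @property
    def blood(self) -> float:
        return float(self.node_temperature[BLOOD])

    def in_band(self) -> bool:
        lo, hi = TEMP_BAND
        return bool(np.all((self.node_temperature >= lo) & (self.node_temperature <= hi)))


@dataclass(frozen=True)
class ControlSignals:
    """Active-system effector outputs.

    ``sweat``: evaporative heat demand per segment (W, >=0);
    ``shiver``: extra metabolic heat per segment's muscle node (W, >=0);
    ``bf_mult``: skin blood-flow multiplier per segment (>0, 1 = basal).
    """

    sweat: np.ndarray
    shiver: np.ndarray
    bf_mult: np.ndarray

    @classmethod
    def zero(cls) -> "ControlSignals":
        return cls(
            sweat=np.zeros(N_SEGMENTS),
            shiver=np.zeros(N_SEGMENTS),
            bf_mult=np.ones(N_SEGMENTS),
        )


@dataclass(frozen=True)
class ControlParams:
    sig_core_gain: float
    sig_skin_gain: float
    sweat_gain_w: float
    sweat_max_w: float
    shiver_gain_w: float
    shiver_max_w: float
    vaso_core_gain: float
    vaso_skin_gain: float
    dilation_gain: float
    constriction_gain: float
    bf_mult_min: float
    bf_mult_max: float


@dataclass(frozen=True)
class PhysioParams:
    """Derived node-level parameter set for the thermoregulation model."""

    # per-segment (length 14)
    area: np.ndarray                 # m^2
    clothing: np.ndarray             # m^2 K / W
    skin_setpoint: np.ndarray        # degC
    receptor_w: np.ndarray           # skin-sensor weights, sum 1
    sweat_w: np.ndarray              # sweat distribution, sum 1
    shiver_w: np.ndarray             # shiver distribution, sum 1
    # per-node (length 57)
    capacity: np.ndarray             # J/K
    met_basal: np.ndarray            # W
    bf_basal: np.ndarray             # L/h
    # per-segment inter-layer conductances, shape (14, 3):
    # columns core-muscle, muscle-fat, fat-skin, W/K
    conductance: np.ndarray
    # scalars
    total_area: float                # m^2
    met_total: float                 # W
    core_setpoint: float             # degC
    emissivity: float
    lewis_ratio: float               # K/kPa
    clothing_icl: float
    skin_diffusion_fraction: float
    height: float                    # m
    controls: ControlParams = field(repr=False, default=None)  # type: ignore[assignment]

    def with_clothing(self, r_cl: float | np.ndarray) -> "PhysioParams":
        """Copy with the per-segment clothing resistance replaced.

        A scalar applies the same resistance to every segment (e.g. the
        0.775 m^2 K/W configuration printed for the reference study).
        """
        r = np.broadcast_to(np.asarray(r_cl, dtype=float), (N_SEGMENTS,)).copy()
        return replace(self, clothing=r)


def _segment_records(raw: dict) -> list[dict]:
    segs = raw["segments"]
    missing = [s.value for s in SEGMENTS if s.value not in segs]
    if missing:
        raise ConfigurationError(f"physiology file missing segments: {missing}")
    return [segs[s.value] for s in SEGMENTS]


def load_physio_params(path: str | Path | None = None) -> PhysioParams:
    """Load the physiology parameter set (packaged default or a YAML file)."""
    if path is None:
        text = resources.files("cabtherm.data").joinpath("physiology.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    body, recs = raw["body"], _segment_records(raw)

    area = np.array([r["area_m2"] for r in recs])
    total_area = float(area.sum())
    met_total = body["metabolic_rate_w_per_m2"] * total_area

    mass_frac = np.array([r["mass_fraction"] for r in recs])
    mass_frac = mass_frac / mass_frac.sum()
    layer_frac = np.array([r["layer_mass_fractions"] for r in recs])  # (14,4)
    node_mass = (body["mass_kg"] - body["blood_mass_kg"]) * mass_frac[:, None] * (
        layer_frac / layer_frac.sum(axis=1, keepdims=True)
    )
    capacity = np.empty(N_NODES)
    capacity[:BLOOD] = (node_mass * body["specific_heat_j_per_kgk"]).ravel()
    capacity[BLOOD] = body["blood_mass_kg"] * body["blood_specific_heat_j_per_kgk"]

    met_w = np.array([r["met_weights"] for r in recs])  # (14,4)
    met_basal = np.zeros(N_NODES)
    met_basal[:BLOOD] = (met_w / met_w.sum() * met_total).ravel()

    bf_basal = np.zeros(N_NODES)
    tissue = met_basal[:BLOOD].reshape(N_SEGMENTS, 4)
    bf = np.zeros_like(tissue)
    bf[:, CORE] = tissue[:, CORE] * body["bf_l_per_h_per_w"]
    bf[:, MUSCLE] = tissue[:, MUSCLE] * body["bf_l_per_h_per_w"]
    bf[:, FAT] = tissue[:, FAT] * body["fat_bf_l_per_h_per_w"]
    bf[:, SKIN] = np.array([r["skin_basal_bf_l_per_h"] for r in recs])
    bf_basal[:BLOOD] = bf.ravel()

    conductance = np.array([r["conductance_w_per_m2k"] for r in recs]) * area[:, None]

    def norm(key: str) -> np.ndarray:
        w = np.array([r[key] for r in recs], dtype=float)
        return w / w.sum()

    ctrl = ControlParams(**raw["controls"])
    return PhysioParams(
        area=area,
        clothing=np.array([r["clothing_m2k_per_w"] for r in recs], dtype=float),
        skin_setpoint=np.array([r["skin_setpoint_c"] for r in recs], dtype=float),
        receptor_w=norm("receptor_weight"),
        sweat_w=norm("sweat_weight"),
        shiver_w=norm("shiver_weight"),
        capacity=capacity,
        met_basal=met_basal,
        bf_basal=bf_basal,
        conductance=conductance,
        total_area=total_area,
        met_total=met_total,
        core_setpoint=body["core_setpoint_c"],
        emissivity=body["emissivity"],
        lewis_ratio=body["lewis_ratio_k_per_kpa"],
        clothing_icl=body["clothing_vapour_permeation"],
        skin_diffusion_fraction=body["skin_diffusion_fraction"],
        height=body["height_m"],
        controls=ctrl,
    )


#: Initial skin temperatures of the reference driver, degC (these double
#: as the default sensation/control set-points).
INITIAL_SKIN = {
    SegmentId.HEAD: 36.0,
    SegmentId.CHEST: 35.0,
    SegmentId.L_UPPER_ARM: 35.0,
    SegmentId.R_UPPER_ARM: 35.0,
    SegmentId.L_LOWER_ARM: 35.0,
    SegmentId.R_LOWER_ARM: 35.0,
    SegmentId.L_HAND: 35.0,
    SegmentId.R_HAND: 35.0,
    SegmentId.L_UPPER_LEG: 35.0,
    SegmentId.R_UPPER_LEG: 35.0,
    SegmentId.L_LOWER_LEG: 34.0,
    SegmentId.R_LOWER_LEG: 34.0,
    SegmentId.L_FOOT: 36.0,
    SegmentId.R_FOOT: 36.0,
}


def default_initial_state(params: PhysioParams | None = None) -> BodyState:
    """Reference initial state: tabulated skin temperatures, warm interior."""
    t = np.empty(N_NODES)
    nodes = t[:BLOOD].reshape(N_SEGMENTS, 4)
    nodes[:, CORE] = 36.8
    nodes[:, MUSCLE] = 36.3
    nodes[:, FAT] = 35.8
    nodes[:, SKIN] = [INITIAL_SKIN[s] for s in SEGMENTS]
    t[BLOOD] = 36.8
    return BodyState(node_temperature=t, time=0.0)
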