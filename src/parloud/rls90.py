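"""RLS-90 road-traffic emission and receiver levels.

The German RLS-90 guideline expresses a road's idealised mean emission
level 25 m from the lane as

    Lm,E = 37.3 + 10 log10[Q (1 + 0.082 P)]

for traffic volume Q (vehicles/hour) and heavy-truck percentage P
(vehicles over 2.8 t), then corrects for the speed limit (R_SL), road
surface (R_RS), gradient (R_RG), building absorption (R_E), distance
and air absorption (R_DA), ground and meteorology (R_GA), and
topography (R_TB), and finally adds the traffic-light surcharge K:

    Lm = Lm,E + R_SL + R_RS + R_RG + R_E + R_DA + R_GA + R_TB
    Lr = Lm + K

The speed correction is zero at the reference speeds (100 km/h cars,
80 km/h trucks).  R_RS, R_E, R_DA, R_GA and R_TB are site-specific
inputs here (defaulting to 0); the guideline's propagation geometry is
out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RoadSegment",
    "EmissionResult",
    "emission_level",
    "speed_correction",
    "gradient_correction",
    "receiver_level",
    "combine_levels",
]

_SPEED_RANGE = (30.0, 130.0)


@dataclass(frozen=True)
class RoadSegment:
    """One road lane/segment with its RLS-90 inputs."""

    q_veh_h: float                # traffic volume per hour
    p_trucks_pct: float = 0.0     # % heavy vehicles (> 2.8 t)
    v_car: float = 100.0          # km/h speed limit, light vehicles
    v_truck: float = 80.0         # km/h speed limit, heavy vehicles
    gradient_pct: float = 0.0
    r_rs: float = 0.0             # road surface
    r_e: float = 0.0              # building absorption
    r_da: float = 0.0             # distance + air absorption
    r_ga: float = 0.0             # ground + atmosphere
    r_tb: float = 0.0             # topography + buildings
    k_intersection: float = 0.0

    def __post_init__(self):
        if self.q_veh_h < 0:
            raise ValueError("traffic volume must be non-negative")
        if not 0.0 <= self.p_trucks_pct <= 100.0:
            raise ValueError("truck percentage must lie in [0, 100]")
        for v in (self.v_car, self.v_truck):
            if not _SPEED_RANGE[0] <= v <= _SPEED_RANGE[1]:
                raise ValueError("speed limits must lie within 30-130 km/h")


@dataclass(frozen=True)
class EmissionResult:
    """All levels and intermediates for one segment, in dB(A)."""

    lm_e: float
    r_sl: float
    r_rg: float
    lm: float
    lr: float
    l_car: float
    l_truck: float
    d: float


def emission_level(q_veh_h: float, p_trucks_pct: float = 0.0) -> float:
    """Idealised emission level Lm,E at 25 m (dB)."""
    if q_veh_h <= 0:
        raise ValueError("emission level undefined for zero traffic volume")
    if not 0.0 <= p_trucks_pct <= 100.0:
        raise ValueError("truck percentage must lie in [0, 100]")
    return 37.3 + 10.0 * np.log10(q_veh_h * (1.0 + 0.082 * p_trucks_pct))


def speed_correction(v_car: float, v_truck: float, p_trucks_pct: float = 0.0):
    """Speed-limit correction R_SL and its intermediates (dB).

    Returns ``(r_sl, l_car, l_truck, d)`` with
    L_car = 27.7 + 10 log10[1 + (0.02 v_car)^3],
    L_truck = 23.1 + 12.5 log10(v_truck), D = L_truck - L_car and
    R_SL = L_car - 37.3 + 10 log10[(100 + (10^{0.1 D} - 1) P) / (100 + 8.23 P)].
    """
    for v in (v_car, v_truck):
        if not _SPEED_RANGE[0] <= v <= _SPEED_RANGE[1]:
            raise ValueError("speed limits must lie within 30-130 km/h")
    p = p_trucks_pct
    l_car = 27.7 + 10.0 * np.log10(1.0 + (0.02 * v_car) ** 3)
    l_truck = 23.1 + 12.5 * np.log10(v_truck)
    d = l_truck - l_car
    r_sl = l_car - 37.3 + 10.0 * np.log10(
        (100.0 + (10.0 ** (0.1 * d) - 1.0) * p) / (100.0 + 8.23 * p)
    )
    return float(r_sl), float(l_car), float(l_truck), float(d)


def gradient_correction(gradient_pct: float) -> float:
    """Road-gradient correction R_RG: 0.6 g - 3 above 5 %, else 0."""
    g = float(gradient_pct)
    return 0.6 * g - 3.0 if g > 5.0 else 0.0


def receiver_level(segment: RoadSegment) -> EmissionResult:
    """Chain emission and corrections into the receiver level Lr."""
    lm_e = emission_level(segment.q_veh_h, segment.p_trucks_pct)
    r_sl, l_car, l_truck, d = speed_correction(
        segment.v_car, segment.v_truck, segment.p_trucks_pct
    )
    r_rg = gradient_correction(segment.gradient_pct)
    lm = (
        lm_e + r_sl + segment.r_rs + r_rg
        + segment.r_e + segment.r_da + segment.r_ga + segment.r_tb
    )
    lr = lm + segment.k_intersection
    return EmissionResult(
        lm_e=float(lm_e), r_sl=r_sl, r_rg=r_rg, lm=float(lm), lr=float(lr),
        l_car=l_car, l_truck=l_truck, d=d,
    )


def combine_levels(levels_db) -> float:
    """Energetic (incoherent) combination of per-lane levels."""
    levels = np.asarray(levels_db, dtype=float)
    if levels.size == 0:
        raise ValueError("no levels to combine")
    return float(10.0 * np.log10(np.sum(10.0 ** (levels / 10.0))))


def distance_attenuation(distance_m: float, reference_m: float = 25.0) -> float:
    """Free-field line-source attenuation helper for toy grids.

    Beyond the RLS-90 text proper: a cylindrical-spreading term
    ``-10 log10(d / d_ref)`` suitable for the R_DA input of synthetic
    receiver grids; real projects use the guideline's full geometry.
    """
    d = max(float(distance_m), 1.0)
    return -10.0 * np.log10(d / reference_m)
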