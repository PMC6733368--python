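"""Psychrometric and thermal closures for the granulator energy balance.

The two-compartment model needs four kinds of closure terms:

* vapor state equations (saturation pressure/concentration, chamber vapor
  concentration, mixing ratios),
* enthalpy rates of the mass streams entering/leaving each compartment
  (``H_*`` terms, in W),
* lumped convective heat-transfer rates between bed, air, wall and
  environment (``Q_*`` terms, in W),
* material/equipment property tables.

All quantities are SI internally; temperatures are degrees Celsius at the
interface (converted to kelvin only inside the ideal-gas conversion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Mapping

import yaml

__all__ = [
    "MaterialProperties",
    "EquipmentProperties",
    "R_GAS",
    "M_WATER",
    "saturation_vapor_pressure",
    "vapor_concentration",
    "saturation_concentration",
    "mixing_ratio_to_flow",
    "enthalpy_rates",
    "heat_transfer_rates",
    "load_properties",
    "save_properties",
]

#: Universal gas constant [J/(mol K)]
R_GAS = 8.314462618
#: Molar mass of water [kg/mol]
M_WATER = 0.018015


@dataclass(frozen=True)
class MaterialProperties:
    """Thermophysical property table for the granulated product and streams.

    Specific heats are in J/(kg K): ``cp_s`` dry solids (API + excipients),
    ``cp_wl`` liquid water, ``cp_wg`` water vapor, ``cp_b`` binder solids,
    ``cp_a`` dry air, ``cp_steel`` wall steel.  ``lambda0`` is the latent
    heat of vaporization at the enthalpy reference temperature ``T0`` [degC].
    ``rho_particle`` is the true particle density [kg/m3] used to convert
    the effective particle size into a surface area, and ``D_w`` the
    diffusivity of water vapor in air [m2/s] entering the Ranz-Marshall
    transfer coefficient.  ``rho_air``/``mu_air`` are film air density
    [kg/m3] and dynamic viscosity [Pa s] for the Reynolds/Schmidt numbers.
    """

    cp_s: float = 1200.0
    cp_wl: float = 4186.0
    cp_wg: float = 1900.0
    cp_b: float = 1500.0
    cp_a: float = 1006.0
    cp_steel: float = 500.0
    lambda0: float = 2.45e6
    rho_particle: float = 1500.0
    T0: float = 0.0
    D_w: float = 2.6e-5
    rho_air: float = 1.1
    mu_air: float = 1.85e-5

    def __post_init__(self) -> None:
        for name in (
            "cp_s", "cp_wl", "cp_wg", "cp_b", "cp_a", "cp_steel",
            "lambda0", "rho_particle", "D_w", "rho_air", "mu_air",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"MaterialProperties.{name} must be positive")


@dataclass(frozen=True)
class EquipmentProperties:
    """Lumped description of one granulator.

    ``m_air`` is the dry-air holdup of the chamber [kg] and ``V_chamber``
    its free volume [m3].  ``UA_*`` are lumped heat-transfer conductances
    [W/K] between bed/air/wall/environment; ``UA_bed_air`` couples the bed
    to the fluidization air.  ``A_cross`` is the bed cross-section [m2]
    used for the superficial air velocity.  ``T_env`` is the plant ambient
    temperature [degC] and ``P_atm`` the pressure [Pa].
    """

    m_air: float = 1.8
    V_chamber: float = 1.5
    m_wall: float = 400.0
    UA_bed_wall: float = 15.0
    UA_bed_air: float = 500.0
    UA_air_wall: float = 50.0
    UA_wall_env: float = 20.0
    A_cross: float = 0.5
    T_env: float = 22.0
    P_atm: float = 101325.0

    def __post_init__(self) -> None:
        for name in (
            "m_air", "V_chamber", "m_wall", "UA_bed_wall", "UA_bed_air",
            "UA_air_wall", "UA_wall_env", "A_cross", "P_atm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"EquipmentProperties.{name} must be positive")
        if not math.isfinite(self.T_env):
            raise ValueError("EquipmentProperties.T_env must be finite")


# Arden Buck fit (a Magnus-form curve over liquid water); accurate to well
# under 1% from the triple point up to boiling.
_BUCK_A = 611.21
_BUCK_B = 18.678
_BUCK_C = 234.5
_BUCK_D = 257.14


def saturation_vapor_pressure(T: float) -> float:
    """Saturation vapor pressure over liquid water [Pa] at ``T`` [degC].

    Valid for -20 <= T <= 150 degC; raises ``ValueError`` outside.
    """
    if not (-20.0 <= T <= 150.0):
        raise ValueError(f"temperature {T} degC outside psychrometric validity range [-20, 150]")
    return _BUCK_A * math.exp((_BUCK_B - T / _BUCK_C) * T / (_BUCK_D + T))


def vapor_concentration(m_air_w: float, V: float) -> float:
    """Water-vapor concentration in the chamber [kg/m3]."""
    if m_air_w < 0:
        raise ValueError("water mass in air must be nonnegative")
    if V <= 0:
        raise ValueError("chamber volume must be positive")
    return m_air_w / V


def saturation_concentration(T_surface: float, P: float = 101325.0) -> float:
    """Equilibrium water concentration at a wet surface [kg/m3].

    Ideal-gas conversion of the saturation pressure at the surface
    temperature; ``P`` is accepted for interface symmetry but the vapor
    partial pressure alone sets the concentration.
    """
    p_sat = saturation_vapor_pressure(T_surface)
    return p_sat * M_WATER / (R_GAS * (T_surface + 273.15))


def mixing_ratio_to_flow(x_in: float, F_air: float) -> float:
    """Water mass inflow [kg/s] carried by air at mixing ratio ``x_in``."""
    if x_in < 0 or F_air < 0:
        raise ValueError("mixing ratio and air flow must be nonnegative")
    return x_in * F_air


def enthalpy_rates(
    *,
    F_spray: float,
    w_s: float,
    T_spray: float,
    F_air: float,
    x_in: float,
    T_in: float,
    x_out: float,
    T_air: float,
    m_evap: float,
    T_bed: float,
    props: MaterialProperties,
) -> dict[str, float]:
    """Enthalpy rates [W] of the mass streams crossing compartment borders.

    ``H_spray`` is carried by the binder solution (liquid water + binder
    solids) entering the bed at ``T_spray``; ``H_air_in``/``H_air_out`` by
    the humid air stream (dry air + vapor at the inlet/chamber mixing
    ratio); ``H_evap`` is the latent plus vapor-sensible enthalpy moved
    from bed to air by the evaporating water.
    """
    T0 = props.T0
    H_spray = F_spray * ((1.0 - w_s) * props.cp_wl + w_s * props.cp_b) * (T_spray - T0)
    H_air_in = F_air * (props.cp_a + x_in * props.cp_wg) * (T_in - T0)
    H_air_out = F_air * (props.cp_a + x_out * props.cp_wg) * (T_air - T0)
    H_evap = m_evap * (props.lambda0 + props.cp_wg * (T_bed - T0))
    return {
        "H_spray": H_spray,
        "H_air_in": H_air_in,
        "H_air_out": H_air_out,
        "H_evap": H_evap,
    }


def heat_transfer_rates(
    T_bed: float,
    T_air: float,
    T_wall: float,
    equip: EquipmentProperties,
) -> dict[str, float]:
    """Lumped convective heat-transfer rates [W].

    Sign convention: ``Q_x_y = UA_xy * (T_x - T_y)``, positive when heat
    flows from x to y.
    """
    return {
        "Q_bed_wall": equip.UA_bed_wall * (T_bed - T_wall),
        "Q_bed_air": equip.UA_bed_air * (T_bed - T_air),
        "Q_air_wall": equip.UA_air_wall * (T_air - T_wall),
        "Q_wall_env": equip.UA_wall_env * (T_wall - equip.T_env),
    }


def load_properties(path) -> tuple[MaterialProperties, EquipmentProperties]:
    """Read a YAML property table with ``material:`` and ``equipment:`` blocks.

    Missing keys fall back to the documented defaults.
    """
    with open(path) as fh:
        raw: Mapping = yaml.safe_load(fh) or {}
    mat = MaterialProperties(**(raw.get("material") or {}))
    eq = EquipmentProperties(**(raw.get("equipment") or {}))
    return mat, eq


def save_properties(path, props: MaterialProperties, equip: EquipmentProperties) -> None:
    """Write a property table readable by :func:`load_properties`."""
    with open(path, "w") as fh:
        yaml.safe_dump({"material": asdict(props), "equipment": asdict(equip)}, fh, sort_keys=False)
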