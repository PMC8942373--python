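"""Physical constants and unit conversions.

All elastic constants in this package are stored in thermal energy units
(kBT) at a stated temperature; conversions to mechanical (pN·nm) or molar
(kJ/mol) units are pure functions of temperature, collected here so that
every module shares one registry.
"""

from __future__ import annotations

import math

#: Boltzmann constant, pN·nm/K.
KB_PN_NM = 1.380649e-2

#: Gas constant, kJ/(mol·K).
R_KJ_MOL = 8.31446261815324e-3

#: Reference temperature for thermal-energy conversions: 22 °C.
T_REF = 295.15

#: Elementary charge, C.
E_CHARGE = 1.602176634e-19

#: Vacuum permittivity, C²/(J·m).
EPS0 = 8.8541878128e-12

#: Relative dielectric constant of water near room temperature.
WATER_EPS_R = 78.3


def kbt_pn_nm(temperature: float = T_REF) -> float:
    """Thermal energy kBT in pN·nm at ``temperature`` (K).

    At 295.15 K this is 4.075 pN·nm.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_PN_NM * temperature


def kbt_kj_mol(temperature: float = T_REF) -> float:
    """Thermal energy kBT in kJ/mol at ``temperature`` (K).

    At 295.15 K this is 2.454 kJ/mol.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_KJ_MOL * temperature


def bjerrum_length(temperature: float = T_REF, eps_r: float = WATER_EPS_R) -> float:
    """Bjerrum length in nm: separation at which two unit charges interact with kBT.

    l_B = e² / (4π ε0 εr kB T) ≈ 0.7 nm in water at room temperature.
    """
    if temperature <= 0 or eps_r <= 0:
        raise ValueError("temperature and eps_r must be positive")
    kbt_j = 1.380649e-23 * temperature
    lb_m = E_CHARGE**2 / (4.0 * math.pi * EPS0 * eps_r * kbt_j)
    return lb_m * 1e9


def debye_length(c_salt: float, temperature: float = T_REF,
                 eps_r: float = WATER_EPS_R) -> float:
    """Debye screening length κ⁻¹ in nm for a 1:1 salt at molarity ``c_salt``.

    κ² = 8π l_B n with n the number density of each ion species; for water at
    298 K this reduces to the familiar κ⁻¹ ≈ 0.304/√c nm.

    Parameters
    ----------
    c_salt : float
        Monovalent salt concentration, mol/L.
    temperature : float
        Absolute temperature, K.
    """
    if c_salt <= 0:
        raise ValueError(f"salt concentration must be positive, got {c_salt}")
    lb = bjerrum_length(temperature, eps_r)
    # number density per nm^3 of one ion species: c [mol/L] * N_A / 1e24
    n_per_nm3 = c_salt * 6.02214076e23 / 1e24
    kappa_sq = 8.0 * math.pi * lb * n_per_nm3
    return 1.0 / math.sqrt(kappa_sq)


def deg_to_rad(x: float) -> float:
    return x * math.pi / 180.0


def rad_to_deg(x: float) -> float:
    return x * 180.0 / math.pi
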