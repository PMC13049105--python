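"""Seawater CO2-system solver for the measured pair (total alkalinity, total-scale pH).

The vent-site sensors log pH on the total scale; discrete bottle samples give
total alkalinity (A_T).  From that pair plus temperature and salinity this
module derives the remaining carbonate-system parameters: dissolved inorganic
carbon (C_T), pCO2, the carbonate species, and the calcite/aragonite
saturation states.  Because [H+] is measured directly, the solution is
algebraic — no iteration is needed — and a bisection pH-recovery routine is
provided as an independent consistency oracle.

Default equilibrium constants follow the formulations most commonly used for
surface Mediterranean work: Lueker et al. (2000) for carbonic acid, Dickson
(1990) for bisulfate and boric acid, Perez & Fraga (1987) for HF, Millero
(1995) for water, Weiss (1974) for CO2 solubility, Uppstrom (1974) boron,
Mucci (1983) solubility products, and calcium proportional to S/35.  All
computation stays on the total pH scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SeawaterState",
    "ConstantsSet",
    "CarbonateResult",
    "equilibrium_constants",
    "solve_from_at_ph",
    "saturation_state",
    "apply_sensor_offset",
    "ph_from_at_ct",
]

#: Default practical salinity assumed when a record carries none
#: (Mediterranean surface water near the study reefs).
DEFAULT_SALINITY = 38.0


class CarbonateError(ValueError):
    """Raised when the carbonate system cannot be solved for an input."""


@dataclass(frozen=True)
class SeawaterState:
    """One water sample / sensor record.

    Parameters
    ----------
    temperature : float
        In-situ temperature, degrees C.
    salinity : float
        Practical salinity (dimensionless).
    alkalinity_total : float
        Total alkalinity, umol per kg of seawater.
    ph_total : float
        pH on the total hydrogen-ion scale.
    pressure : float
        Pressure in dbar (0 at the surface; the tiles sit at 0.5-3 m so the
        default of 0 is retained throughout).
    salinity_defaulted : bool
        True when salinity was not measured and the package default was used;
        propagated into output metadata.
    """

    temperature: float
    salinity: float
    alkalinity_total: float
    ph_total: float
    pressure: float = 0.0
    salinity_defaulted: bool = False

    def __post_init__(self):
        if not -2.0 <= self.temperature <= 40.0:
            raise CarbonateError(f"temperature {self.temperature} outside [-2, 40] C")
        if not 0.0 <= self.salinity <= 45.0:
            raise CarbonateError(f"salinity {self.salinity} outside [0, 45]")
        if not self.alkalinity_total > 0:
            raise CarbonateError("alkalinity_total must be > 0")
        if not 3.0 <= self.ph_total <= 9.5:
            raise CarbonateError(f"ph_total {self.ph_total} outside [3, 9.5]")


@dataclass(frozen=True)
class ConstantsSet:
    """Equilibrium constants and total element concentrations at one T/S/P.

    Equilibrium constants are on the total pH scale (except ``ks``, which is
    defined on the free scale and anchors the scale conversion); element
    totals are mol per kg of seawater.
    """

    k0: float  # CO2 solubility, mol kg-1 atm-1
    k1: float  # H2CO3 first dissociation
    k2: float  # second dissociation
    kb: float  # boric acid
    kw: float  # water
    ks: float  # bisulfate (free scale)
    kf: float  # hydrogen fluoride
    total_boron: float
    total_sulfate: float
    total_fluoride: float
    total_calcium: float
    ksp_calcite: float
    ksp_aragonite: float
    constant_choice: str = "lueker"

    def __post_init__(self):
        for name in (
            "k0", "k1", "k2", "kb", "kw", "ks", "kf",
            "total_boron", "total_sulfate", "total_fluoride", "total_calcium",
            "ksp_calcite", "ksp_aragonite",
        ):
            if not getattr(self, name) > 0:
                raise CarbonateError(f"constant {name} must be strictly positive")


@dataclass(frozen=True)
class CarbonateResult:
    """Full speciation derived from an (A_T, pH_T) pair.

    Concentrations in umol per kg seawater; pco2 in uatm; saturation states
    dimensionless.
    """

    ct: float
    pco2: float
    co2_star: float
    hco3: float
    co3: float
    omega_calcite: float
    omega_aragonite: float


_SUPPORTED_CHOICES = ("lueker",)


def equilibrium_constants(state: SeawaterState, constant_choice: str = "lueker") -> ConstantsSet:
    """Evaluate the chosen equilibrium-constant formulations at the record's T/S.

    Only the Lueker-family default set is currently registered; the argument
    exists so alternative families can be added without touching callers.
    Validity of the fits (roughly T in [2, 35] C, S in [19, 43] for Lueker)
    is warned about, not enforced.
    """
    if constant_choice not in _SUPPORTED_CHOICES:
        raise CarbonateError(
            f"unsupported constant_choice {constant_choice!r}; supported: {_SUPPORTED_CHOICES}"
        )

    t_c, s = state.temperature, state.salinity
    t_k = t_c + 273.15
    ln_t = math.log(t_k)

    if not (2.0 <= t_c <= 35.0 and 19.0 <= s <= 43.0):
        warnings.warn(
            f"T={t_c}, S={s} outside the Lueker et al. (2000) fit range",
            stacklevel=2,
        )

    # Weiss (1974) CO2 solubility, mol kg-1 atm-1
    t100 = t_k / 100.0
    ln_k0 = (
        -60.2409 + 93.4517 / t100 + 23.3585 * math.log(t100)
        + s * (0.023517 - 0.023656 * t100 + 0.0047036 * t100 * t100)
    )
    k0 = math.exp(ln_k0)

    # Lueker et al. (2000) carbonic acid, total scale, mol kg-1
    pk1 = 3633.86 / t_k - 61.2172 + 9.67770 * ln_t - 0.011555 * s + 0.0001152 * s * s
    pk2 = 471.78 / t_k + 25.9290 - 3.16967 * ln_t - 0.01781 * s + 0.0001122 * s * s
    k1 = 10.0 ** (-pk1)
    k2 = 10.0 ** (-pk2)

    # Dickson (1990b) boric acid, total scale
    sqrt_s = math.sqrt(s)
    ln_kb = (
        (-8966.90 - 2890.53 * sqrt_s - 77.942 * s + 1.728 * s * sqrt_s - 0.0996 * s * s) / t_k
        + 148.0248 + 137.1942 * sqrt_s + 1.62142 * s
        + (-24.4344 - 25.085 * sqrt_s - 0.2474 * s) * ln_t
        + 0.053105 * sqrt_s * t_k
    )
    kb = math.exp(ln_kb)

    # Millero (1995) water dissociation, total scale
    ln_kw = (
        148.9652 - 13847.26 / t_k - 23.6521 * ln_t
        + (118.67 / t_k - 5.977 + 1.0495 * ln_t) * sqrt_s
        - 0.01615 * s
    )
    kw = math.exp(ln_kw)

    # Dickson (1990a) bisulfate, free scale, mol kg-H2O then to mol kg-sw
    ion = 19.924 * s / (1000.0 - 1.005 * s)
    sqrt_i = math.sqrt(ion)
    ln_ks = (
        -4276.1 / t_k + 141.328 - 23.093 * ln_t
        + (-13856.0 / t_k + 324.57 - 47.986 * ln_t) * sqrt_i
        + (35474.0 / t_k - 771.54 + 114.723 * ln_t) * ion
        - (2698.0 / t_k) * ion * sqrt_i
        + (1776.0 / t_k) * ion * ion
        + math.log(1.0 - 0.001005 * s)
    )
    ks = math.exp(ln_ks)

    # Perez & Fraga (1987) hydrogen fluoride, total scale
    kf = math.exp(874.0 / t_k - 9.68 + 0.111 * sqrt_s)

    # Element totals, mol kg-1 (chlorinity = S / 1.80655)
    total_boron = 0.0004157 * s / 35.0          # Uppstrom (1974)
    total_sulfate = (0.14 / 96.062) * (s / 1.80655)   # Morris & Riley (1966)
    total_fluoride = (0.000067 / 18.998) * (s / 1.80655)  # Riley (1965)
    total_calcium = 0.02128 / 40.087 * (s / 1.80655)      # Riley & Tongudai (1967)

    # Mucci (1983) stoichiometric solubility products
    log10_t = math.log10(t_k)
    log_ksp_cal = (
        -171.9065 - 0.077993 * t_k + 2839.319 / t_k + 71.595 * log10_t
        + (-0.77712 + 0.0028426 * t_k + 178.34 / t_k) * sqrt_s
        - 0.07711 * s + 0.0041249 * s * sqrt_s
    )
    log_ksp_arag = (
        -171.945 - 0.077993 * t_k + 2903.293 / t_k + 71.595 * log10_t
        + (-0.068393 + 0.0017276 * t_k + 88.135 / t_k) * sqrt_s
        - 0.10018 * s + 0.0059415 * s * sqrt_s
    )

    return ConstantsSet(
        k0=k0, k1=k1, k2=k2, kb=kb, kw=kw, ks=ks, kf=kf,
        total_boron=total_boron,
        total_sulfate=total_sulfate,
        total_fluoride=total_fluoride,
        total_calcium=total_calcium,
        ksp_calcite=10.0 ** log_ksp_cal,
        ksp_aragonite=10.0 ** log_ksp_arag,
        constant_choice=constant_choice,
    )


def _carbonate_alkalinity(at_mol: float, h_total: float, k: ConstantsSet) -> float:
    """Carbonate alkalinity (mol/kg) left after removing non-carbonate terms.

    A_T = [HCO3] + 2[CO3] + [B(OH)4] + [OH] - [H]_free - [HSO4] - [HF].
    """
    h_free = h_total / (1.0 + k.total_sulfate / k.ks)
    boh4 = k.total_boron * k.kb / (k.kb + h_total)
    oh = k.kw / h_total
    hso4 = k.total_sulfate / (1.0 + k.ks / h_free)
    hf = k.total_fluoride / (1.0 + k.kf / h_total)
    return at_mol - boh4 - oh + h_free + hso4 + hf


def solve_from_at_ph(state: SeawaterState, constants: ConstantsSet | None = None) -> CarbonateResult:
    """Solve speciation from (A_T, pH_T) algebraically.

    With [H+] known, carbonate alkalinity follows by subtracting the borate,
    water and minor acid-base contributions from A_T, and the three carbon
    species follow from K1/K2.
    """
    k = constants if constants is not None else equilibrium_constants(state)
    h = 10.0 ** (-state.ph_total)
    at_mol = state.alkalinity_total * 1e-6

    ca_alk = _carbonate_alkalinity(at_mol, h, k)
    if ca_alk <= 0:
        raise CarbonateError(
            "carbonate alkalinity non-positive at the given pH: the borate/water "
            "terms exceed total alkalinity (pathological A_T-pH pair)"
        )

    # CA = [HCO3](1 + 2 K2/H)
    hco3 = ca_alk / (1.0 + 2.0 * k.k2 / h)
    co3 = hco3 * k.k2 / h
    co2_star = hco3 * h / k.k1
    ct = co2_star + hco3 + co3
    pco2_uatm = co2_star / k.k0 * 1e6

    omega_c, omega_a = saturation_state(co3 * 1e6, k)

    return CarbonateResult(
        ct=ct * 1e6,
        pco2=pco2_uatm,
        co2_star=co2_star * 1e6,
        hco3=hco3 * 1e6,
        co3=co3 * 1e6,
        omega_calcite=omega_c,
        omega_aragonite=omega_a,
    )


def saturation_state(co3_umol: float, constants: ConstantsSet) -> tuple[float, float]:
    """Calcite and aragonite saturation states Omega = [Ca][CO3]/Ksp.

    ``co3_umol`` is umol/kg; calcium comes from the salinity-proportional
    relation stored in the constants set.
    """
    if co3_umol < 0:
        raise CarbonateError("co3 must be >= 0")
    co3 = co3_umol * 1e-6
    ca = constants.total_calcium
    return (
        ca * co3 / constants.ksp_calcite,
        ca * co3 / constants.ksp_aragonite,
    )


def apply_sensor_offset(ph_series, offset: float):
    """Apply a post-hoc calibration offset to a pH series.

    Returns ``(corrected, metadata)`` where metadata records the offset, as
    every downstream table should carry it.  The offset is the mean deviation
    of the sensor against reference material (e.g. TRIS buffer checks).
    """
    if not np.isfinite(offset):
        raise CarbonateError("offset must be finite")
    corrected = np.asarray(ph_series, dtype=float) + offset
    return corrected, {"ph_offset_applied": float(offset)}


def ph_from_at_ct(
    alkalinity_total: float,
    ct: float,
    temperature: float,
    salinity: float,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> float:
    """Recover total-scale pH from (A_T, C_T) by bisection.

    Independent oracle for :func:`solve_from_at_ph`: the residual
    A_T(pH; C_T) - A_T is monotone in pH, so plain bisection over
    pH in [3, 9.5] converges unconditionally.  ``alkalinity_total`` and
    ``ct`` in umol/kg.
    """
    k = equilibrium_constants(
        SeawaterState(
            temperature=temperature,
            salinity=salinity,
            alkalinity_total=alkalinity_total,
            ph_total=8.0,
        )
    )
    at_mol = alkalinity_total * 1e-6
    ct_mol = ct * 1e-6

    def residual(ph: float) -> float:
        h = 10.0 ** (-ph)
        denom = h * h + k.k1 * h + k.k1 * k.k2
        hco3 = ct_mol * k.k1 * h / denom
        co3 = ct_mol * k.k1 * k.k2 / denom
        h_free = h / (1.0 + k.total_sulfate / k.ks)
        boh4 = k.total_boron * k.kb / (k.kb + h)
        oh = k.kw / h
        hso4 = k.total_sulfate / (1.0 + k.ks / h_free)
        hf = k.total_fluoride / (1.0 + k.kf / h)
        return hco3 + 2.0 * co3 + boh4 + oh - h_free - hso4 - hf - at_mol

    lo, hi = 3.0, 9.5
    f_lo, f_hi = residual(lo), residual(hi)
    if f_lo * f_hi > 0:
        raise CarbonateError("no pH root in [3, 9.5] for the given (A_T, C_T)")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = residual(mid)
        if f_lo * f_mid <= 0:
            hi = mid
        else:
            lo, f_lo = mid, f_mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)
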