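"""Seawater CO2-system speciation from measured pH and total alkalinity.

Solves the marine carbonate system at surface pressure for samples whose pH
(total hydrogen-ion scale) and total alkalinity (A_T) were measured directly,
which is the standard monitoring configuration of flow-through ocean
acidification exposure systems.  With pH known, the proton condition is
linear in dissolved inorganic carbon, so the speciation has a closed form:
every non-carbonate alkalinity contribution (borate, hydroxide, free proton,
bisulfate, hydrogen fluoride) is evaluated at the measured pH, subtracted
from A_T to give carbonate alkalinity, and DIC follows from the carbonic
acid equilibria.

Equilibrium constants (all on the total pH scale, mol/kg-seawater):

* K1, K2 — Lueker, Dickson & Keeling (2000) refit of the Mehrbach constants
* KHSO4  — Dickson (1990)
* KB     — Dickson (1990)
* KW     — Millero (1995)
* K0     — Weiss (1974) CO2 solubility
* Ksp    — Mucci (1983) stoichiometric calcite/aragonite solubility
* B_T    — Uppström (1974); S_T Morris & Riley (1966); F_T Riley (1965)
* Ca²⁺   — Riley & Tongudai (1967) calcium-to-chlorinity ratio

Phosphate and silicate alkalinity are taken as zero (not measured in the
monitoring tables this module ingests) and pCO2 is reported as a partial
pressure in μatm without a fugacity correction.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "STUDY_WATER_MEASUREMENTS",
    "SeawaterSample",
    "EquilibriumConstantSet",
    "CarbonateSpeciation",
    "compute_constants",
    "solve_speciation",
    "saturation_state",
    "total_alkalinity",
    "speciate_table",
]

# Measured treatment-level water chemistry of the exposure experiment
# (directly measured monitoring means: pH total scale, temperature °C,
# salinity, total alkalinity μmol/kg); the derived CO2-system state is what
# solve_speciation computes from these.
STUDY_WATER_MEASUREMENTS = pd.DataFrame(
    [
        {"sample_id": "400", "ph_total": 8.02, "temperature_c": 12.97, "salinity": 29.9, "alkalinity_umol_kg": 2085.4},
        {"sample_id": "800", "ph_total": 7.73, "temperature_c": 12.92, "salinity": 29.9, "alkalinity_umol_kg": 2086.4},
        {"sample_id": "1000", "ph_total": 7.63, "temperature_c": 12.82, "salinity": 29.9, "alkalinity_umol_kg": 2084.9},
        {"sample_id": "2800", "ph_total": 7.29, "temperature_c": 12.87, "salinity": 29.9, "alkalinity_umol_kg": 2085.6},
    ]
)

# valid measurement ranges for the constant fits used here
_S_RANGE = (0.0, 45.0)
_T_RANGE = (-2.0, 40.0)
_PH_RANGE = (6.0, 9.5)


@dataclass(frozen=True)
class SeawaterSample:
    """One water-chemistry measurement: the four directly measured inputs."""

    salinity: float
    temperature: float          # °C
    ph_total: float             # total hydrogen-ion scale
    total_alkalinity: float     # μmol/kg-SW
    pressure: float = 0.0       # dbar, surface only

    def __post_init__(self) -> None:
        if not _S_RANGE[0] < self.salinity < _S_RANGE[1]:
            raise ValueError(f"salinity {self.salinity} outside {_S_RANGE}")
        if not _T_RANGE[0] < self.temperature < _T_RANGE[1]:
            raise ValueError(f"temperature {self.temperature} outside {_T_RANGE}")
        if not _PH_RANGE[0] < self.ph_total < _PH_RANGE[1]:
            raise ValueError(f"ph_total {self.ph_total} outside {_PH_RANGE}")
        if not self.total_alkalinity > 0:
            raise ValueError("total_alkalinity must be positive")
        if self.pressure != 0.0:
            raise ValueError("only surface pressure (0 dbar) is supported")


@dataclass(frozen=True)
class EquilibriumConstantSet:
    """Thermodynamic constants and conservative totals at a given (S, T).

    Dissociation constants are on the total pH scale in mol/kg-SW; k0 in
    mol/kg/atm; solubility products in (mol/kg)²; totals in mol/kg-SW.
    """

    k0: float
    k1: float
    k2: float
    kb: float
    kw: float
    ks: float
    kf: float
    ksp_calcite: float
    ksp_aragonite: float
    bt: float
    st: float
    ft: float
    ca_total: float

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if not v > 0:
                raise ValueError(f"constant {name} must be positive, got {v}")
        if not self.k1 > self.k2:
            raise ValueError("expected k1 > k2")
        if not self.ksp_aragonite > self.ksp_calcite:
            raise ValueError("expected ksp_aragonite > ksp_calcite")


@dataclass(frozen=True)
class CarbonateSpeciation:
    """Derived CO2-system state; concentrations in μmol/kg-SW, pCO2 in μatm."""

    dic: float
    co2_star: float
    hco3: float
    co3: float
    pco2: float
    omega_calcite: float
    omega_aragonite: float


def compute_constants(salinity: float, temperature: float) -> EquilibriumConstantSet:
    """Evaluate the equilibrium constant set at (S, T), surface pressure.

    Deterministic in its inputs; raises ``ValueError`` outside the validity
    ranges of the fits (see module docstring for the formulations used).
    """
    if not _S_RANGE[0] < salinity < _S_RANGE[1]:
        raise ValueError(f"salinity {salinity} outside {_S_RANGE}")
    if not _T_RANGE[0] < temperature < _T_RANGE[1]:
        raise ValueError(f"temperature {temperature} outside {_T_RANGE}")

    S = float(salinity)
    TK = float(temperature) + 273.15
    lnTK = np.log(TK)
    sqS = np.sqrt(S)

    # Weiss 1974 CO2 solubility, mol/kg/atm
    TK100 = TK / 100.0
    k0 = np.exp(
        -60.2409 + 93.4517 / TK100 + 23.3585 * np.log(TK100)
        + S * (0.023517 - 0.023656 * TK100 + 0.0047036 * TK100**2)
    )

    # Lueker et al. 2000, total scale
    pk1 = 3633.86 / TK - 61.2172 + 9.6777 * lnTK - 0.011555 * S + 0.0001152 * S**2
    pk2 = 471.78 / TK + 25.929 - 3.16967 * lnTK - 0.01781 * S + 0.0001122 * S**2
    k1 = 10.0**-pk1
    k2 = 10.0**-pk2

    ion = 19.924 * S / (1000.0 - 1.005 * S)  # ionic strength

    # Dickson 1990 bisulfate, free scale
    ks = np.exp(
        -4276.1 / TK + 141.328 - 23.093 * lnTK
        + (-13856.0 / TK + 324.57 - 47.986 * lnTK) * np.sqrt(ion)
        + (35474.0 / TK - 771.54 + 114.723 * lnTK) * ion
        - 2698.0 / TK * ion**1.5
        + 1776.0 / TK * ion**2
        + np.log(1.0 - 0.001005 * S)
    )
    st = 0.02824 * S / 35.0 / 96.062  # Morris & Riley 1966

    # Dickson & Riley 1979 HF, free scale (kept free-scale; see solver)
    kf = np.exp(1590.2 / TK - 12.641 + 1.525 * np.sqrt(ion) + np.log(1.0 - 0.001005 * S))
    ft = 0.000067 / 18.998 * S / 1.80655  # Riley 1965

    # Dickson 1990 boric acid, total scale
    kb = np.exp(
        (-8966.90 - 2890.53 * sqS - 77.942 * S + 1.728 * S**1.5 - 0.0996 * S**2) / TK
        + 148.0248 + 137.1942 * sqS + 1.62142 * S
        - (24.4344 + 25.085 * sqS + 0.2474 * S) * lnTK
        + 0.053105 * sqS * TK
    )
    bt = 0.0004157 * S / 35.0  # Uppström 1974

    # Millero 1995 water, seawater scale -> total scale
    kw_sws = np.exp(
        148.9802 - 13847.26 / TK - 23.6521 * lnTK
        + (118.67 / TK - 5.977 + 1.0495 * lnTK) * sqS
        - 0.01615 * S
    )
    sws_over_tot = (1.0 + st / ks + ft / kf) / (1.0 + st / ks)
    kw = kw_sws / sws_over_tot

    # Mucci 1983 solubility products
    log_ksp_c = (
        -171.9065 - 0.077993 * TK + 2839.319 / TK + 71.595 * np.log10(TK)
        + (-0.77712 + 0.0028426 * TK + 178.34 / TK) * sqS
        - 0.07711 * S + 0.0041249 * S**1.5
    )
    log_ksp_a = (
        -171.945 - 0.077993 * TK + 2903.293 / TK + 71.595 * np.log10(TK)
        + (-0.068393 + 0.0017276 * TK + 88.135 / TK) * sqS
        - 0.10018 * S + 0.0059415 * S**1.5
    )

    ca_total = 0.02128 / 40.087 * S / 1.80655  # Riley & Tongudai 1967

    return EquilibriumConstantSet(
        k0=float(k0), k1=float(k1), k2=float(k2), kb=float(kb), kw=float(kw),
        ks=float(ks), kf=float(kf),
        ksp_calcite=float(10.0**log_ksp_c), ksp_aragonite=float(10.0**log_ksp_a),
        bt=float(bt), st=float(st), ft=float(ft), ca_total=float(ca_total),
    )


def saturation_state(co3_umol_kg: float, ca_total: float, ksp: float) -> float:
    """Ω = [Ca²⁺][CO3²⁻]/Ksp with CO3²⁻ in μmol/kg and Ca, Ksp in mol units."""
    if ksp <= 0:
        raise ValueError("ksp must be positive")
    if co3_umol_kg < 0 or ca_total < 0:
        raise ValueError("concentrations must be non-negative")
    return ca_total * (co3_umol_kg * 1e-6) / ksp


def _non_carbonate_alkalinity(h_total: float, c: EquilibriumConstantSet) -> float:
    """Borate + hydroxide − free proton − bisulfate − HF terms, mol/kg."""
    h_free = h_total / (1.0 + c.st / c.ks)
    borate = c.bt * c.kb / (c.kb + h_total)
    oh = c.kw / h_total
    hso4 = c.st / (1.0 + c.ks / h_free)
    hf = c.ft / (1.0 + c.kf / h_free)
    return borate + oh - h_free - hso4 - hf


def solve_speciation(
    sample: SeawaterSample, constants: EquilibriumConstantSet | None = None
) -> CarbonateSpeciation:
    """Closed-form CO2-system solution from (pH, A_T) at the sample's S, T.

    The total-alkalinity balance

        A_T = [HCO3⁻] + 2[CO3²⁻] + [B(OH)4⁻] + [OH⁻] − [H⁺]_free − [HSO4⁻] − [HF]

    is evaluated at the measured pH; with all non-carbonate terms known the
    carbonate alkalinity determines DIC directly.  Raises ``ValueError`` if
    the implied carbonate alkalinity is non-positive (alkalinity and pH
    mutually inconsistent).
    """
    c = constants if constants is not None else compute_constants(
        sample.salinity, sample.temperature
    )
    at = sample.total_alkalinity * 1e-6
    h = 10.0 ** -sample.ph_total

    ca_alk = at - _non_carbonate_alkalinity(h, c)
    if ca_alk <= 0:
        raise ValueError(
            f"non-positive carbonate alkalinity ({ca_alk * 1e6:.1f} μmol/kg) at "
            f"pH {sample.ph_total}, A_T {sample.total_alkalinity}: inputs inconsistent"
        )

    denom = h * h + c.k1 * h + c.k1 * c.k2
    dic = ca_alk * denom / (c.k1 * h + 2.0 * c.k1 * c.k2)
    co2_star = dic * h * h / denom
    hco3 = dic * c.k1 * h / denom
    co3 = dic * c.k1 * c.k2 / denom
    pco2 = co2_star / c.k0 * 1e6  # atm fraction -> μatm via mol/kg / (mol/kg/atm)

    co3_umol = co3 * 1e6
    return CarbonateSpeciation(
        dic=dic * 1e6,
        co2_star=co2_star * 1e6,
        hco3=hco3 * 1e6,
        co3=co3_umol,
        pco2=pco2,
        omega_calcite=saturation_state(co3_umol, c.ca_total, c.ksp_calcite),
        omega_aragonite=saturation_state(co3_umol, c.ca_total, c.ksp_aragonite),
    )


def total_alkalinity(
    speciation: CarbonateSpeciation, ph_total: float, constants: EquilibriumConstantSet
) -> float:
    """Reconstruct A_T (μmol/kg) from a speciation result — round-trip check."""
    h = 10.0**-ph_total
    carb = (speciation.hco3 + 2.0 * speciation.co3) * 1e-6
    return (carb + _non_carbonate_alkalinity(h, constants)) * 1e6


def speciate_table(water: pd.DataFrame) -> pd.DataFrame:
    """Run the speciation solver over a water-chemistry table.

    Expects columns ``sample_id, ph_total, temperature_c, salinity,
    alkalinity_umol_kg``; returns the input columns plus the derived state
    (``pco2_uatm, co3_umol_kg, hco3_umol_kg, co2_umol_kg, dic_umol_kg,
    omega_calcite, omega_aragonite``).
    """
    required = {"sample_id", "ph_total", "temperature_c", "salinity", "alkalinity_umol_kg"}
    missing = required - set(water.columns)
    if missing:
        raise ValueError(f"water-chemistry table missing columns: {sorted(missing)}")
    rows = []
    for rec in water.itertuples(index=False):
        sample = SeawaterSample(
            salinity=rec.salinity,
            temperature=rec.temperature_c,
            ph_total=rec.ph_total,
            total_alkalinity=rec.alkalinity_umol_kg,
        )
        sp = solve_speciation(sample)
        rows.append(
            {
                "sample_id": rec.sample_id,
                "ph_total": rec.ph_total,
                "temperature_c": rec.temperature_c,
                "salinity": rec.salinity,
                "alkalinity_umol_kg": rec.alkalinity_umol_kg,
                "pco2_uatm": sp.pco2,
                "co3_umol_kg": sp.co3,
                "hco3_umol_kg": sp.hco3,
                "co2_umol_kg": sp.co2_star,
                "dic_umol_kg": sp.dic,
                "omega_calcite": sp.omega_calcite,
                "omega_aragonite": sp.omega_aragonite,
            }
        )
    return pd.DataFrame(rows)
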