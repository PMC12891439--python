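"""Seawater carbonate-system solution from pH and total alkalinity.

Given a water sample (pH on the total hydrogen-ion scale, total
alkalinity, temperature, salinity) the solver returns the full carbonate
speciation: DIC, pCO2, bicarbonate, carbonate, aqueous CO2, and the
calcite/aragonite saturation states.

Equilibrium constants follow the conventional set used for coastal
carbonate-system calculations (all converted to the total pH scale):

* K0 (CO2 solubility): Weiss (1974)
* K1, K2 (carbonic acid): Lueker, Dickson & Keeling (2000)
* KB (boric acid): Dickson (1990)
* KW (water): Millero (1995), converted SWS -> total
* KS (bisulfate): Dickson (1990), free scale
* KF (hydrogen fluoride): Dickson & Riley (1979)
* Ksp calcite/aragonite: Mucci (1983)
* Total borate from salinity: Uppstrom (1974); sulfate: Morris & Riley
  (1966); fluoride: Riley (1965); calcium: Riley & Tongudai (1967)

Nutrient (phosphate/silicate) alkalinity is assumed zero — unmeasured in
the field campaign.  Temperature/salinity ranges of the K1/K2 formulation
(2-35 C, 19-43 psu) are enforced as warnings, not errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date as _date

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "WaterSample",
    "CarbonateState",
    "ConstantsSet",
    "equilibrium_constants",
    "solve_from_ph_ta",
    "ph_from_dic_ta",
    "nbs_to_total",
]

R_GAS = 83.14462618  # cm3 bar K-1 mol-1


@dataclass(frozen=True)
class WaterSample:
    """One discrete water sample.

    pH on the total hydrogen-ion scale; TA in umol/kg-SW; temperature in
    deg C; practical salinity.
    """

    date: _date | None
    site: str
    ph_total: float
    ta_umol_kg: float
    temperature_c: float
    salinity_psu: float

    def __post_init__(self) -> None:
        if not 6.0 < self.ph_total < 9.5:
            raise ValueError(f"pH {self.ph_total} outside (6, 9.5)")
        if not 0.0 < self.salinity_psu < 45.0:
            raise ValueError(f"salinity {self.salinity_psu} outside (0, 45)")
        if not self.ta_umol_kg > 0:
            raise ValueError("TA must be positive")


@dataclass(frozen=True)
class CarbonateState:
    """Full carbonate-system solution for one sample (umol/kg and uatm)."""

    DIC_umol_kg: float
    pCO2_uatm: float
    fCO2_uatm: float
    CO3_umol_kg: float
    HCO3_umol_kg: float
    CO2aq_umol_kg: float
    omega_calcite: float
    omega_aragonite: float

    def __post_init__(self) -> None:
        for name in ("DIC_umol_kg", "CO3_umol_kg", "HCO3_umol_kg",
                     "CO2aq_umol_kg", "omega_calcite", "omega_aragonite"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} negative: infeasible solution")


@dataclass(frozen=True)
class ConstantsSet:
    """Equilibrium constants at (T, S), surface pressure, total pH scale
    except KS/KF (free scale, used only for scale conversions)."""

    temperature_c: float
    salinity_psu: float
    K0: float
    K1: float
    K2: float
    KB: float
    KW: float
    KS: float
    KF: float
    Ksp_calcite: float
    Ksp_aragonite: float
    total_borate: float
    total_sulfate: float
    total_fluoride: float
    calcium: float
    fugacity_factor: float
    sws_to_total: float


def equilibrium_constants(temperature_c: float, salinity_psu: float) -> ConstantsSet:
    """Evaluate the constant set at in-situ temperature and salinity."""
    T, S = float(temperature_c), float(salinity_psu)
    if not (2.0 <= T <= 35.0) or not (19.0 <= S <= 43.0):
        warnings.warn(
            f"(T={T} C, S={S}) outside the K1/K2 formulation range "
            "(2-35 C, 19-43 psu); constants extrapolated", stacklevel=2
        )
    TK = T + 273.15
    lnTK = np.log(TK)
    sqS = np.sqrt(S)

    # ionic strength and totals (mol/kg-SW)
    IonS = 19.924 * S / (1000.0 - 1.005 * S)
    TB = 0.000232 / 10.811 * S / 1.80655      # Uppstrom 1974
    TS = 0.14 / 96.062 * S / 1.80655          # Morris & Riley 1966
    TF = 0.000067 / 18.998 * S / 1.80655      # Riley 1965
    Ca = 0.02128 / 40.087 * S / 1.80655       # Riley & Tongudai 1967

    # KS, Dickson 1990a, free scale, mol/kg-SW
    lnKS = (
        -4276.1 / TK + 141.328 - 23.093 * lnTK
        + (-13856.0 / TK + 324.57 - 47.986 * lnTK) * np.sqrt(IonS)
        + (35474.0 / TK - 771.54 + 114.723 * lnTK) * IonS
        - 2698.0 / TK * IonS ** 1.5
        + 1776.0 / TK * IonS ** 2
        + np.log(1.0 - 0.001005 * S)
    )
    KS = np.exp(lnKS)

    # KF, Dickson & Riley 1979, free scale, mol/kg-SW
    lnKF = 1590.2 / TK - 12.641 + 1.525 * np.sqrt(IonS) + np.log(1.0 - 0.001005 * S)
    KF = np.exp(lnKF)

    sws_to_total = (1.0 + TS / KS) / (1.0 + TS / KS + TF / KF)

    # K0, Weiss 1974, mol/kg-SW/atm
    TK100 = TK / 100.0
    lnK0 = (
        -60.2409 + 93.4517 / TK100 + 23.3585 * np.log(TK100)
        + S * (0.023517 - 0.023656 * TK100 + 0.0047036 * TK100 ** 2)
    )
    K0 = np.exp(lnK0)

    # K1, K2: Lueker et al. 2000, total scale
    pK1 = 3633.86 / TK - 61.2172 + 9.67770 * lnTK - 0.011555 * S + 0.0001152 * S ** 2
    pK2 = 471.78 / TK + 25.9290 - 3.16967 * lnTK - 0.01781 * S + 0.0001122 * S ** 2
    K1 = 10.0 ** -pK1
    K2 = 10.0 ** -pK2

    # KB, Dickson 1990b, total scale
    lnKB = (
        (-8966.90 - 2890.53 * sqS - 77.942 * S + 1.728 * S ** 1.5 - 0.0996 * S ** 2) / TK
        + 148.0248 + 137.1942 * sqS + 1.62142 * S
        + (-24.4344 - 25.085 * sqS - 0.2474 * S) * lnTK
        + 0.053105 * sqS * TK
    )
    KB = np.exp(lnKB)

    # KW, Millero 1995 (SWS), converted to total scale
    lnKW_sws = (
        148.9802 - 13847.26 / TK - 23.6521 * lnTK
        + (118.67 / TK - 5.977 + 1.0495 * lnTK) * sqS
        - 0.01615 * S
    )
    KW = np.exp(lnKW_sws) * sws_to_total

    # Ksp, Mucci 1983
    log10TK = np.log10(TK)
    log10Kspc = (
        -171.9065 - 0.077993 * TK + 2839.319 / TK + 71.595 * log10TK
        + (-0.77712 + 0.0028426 * TK + 178.34 / TK) * sqS
        - 0.07711 * S + 0.0041249 * S ** 1.5
    )
    log10Kspa = (
        -171.945 - 0.077993 * TK + 2903.293 / TK + 71.595 * log10TK
        + (-0.068393 + 0.0017276 * TK + 88.135 / TK) * sqS
        - 0.10018 * S + 0.0059415 * S ** 1.5
    )
    Kspc = 10.0 ** log10Kspc
    Kspa = 10.0 ** log10Kspa

    # fugacity factor for pCO2 <-> fCO2 (Weiss 1974 virial coefficients)
    b_virial = -1636.75 + 12.0408 * TK - 0.0327957 * TK ** 2 + 3.16528e-5 * TK ** 3
    delta = 57.7 - 0.118 * TK
    fugfac = np.exp((b_virial + 2.0 * delta) * 1.01325 / (R_GAS * TK))

    return ConstantsSet(
        temperature_c=T, salinity_psu=S, K0=float(K0), K1=float(K1),
        K2=float(K2), KB=float(KB), KW=float(KW), KS=float(KS), KF=float(KF),
        Ksp_calcite=float(Kspc), Ksp_aragonite=float(Kspa),
        total_borate=float(TB), total_sulfate=float(TS),
        total_fluoride=float(TF), calcium=float(Ca),
        fugacity_factor=float(fugfac), sws_to_total=float(sws_to_total),
    )


def nbs_to_total(ph_nbs: float, temperature_c: float, salinity_psu: float) -> float:
    """Approximate NBS -> total scale conversion via the activity
    coefficient fH of Takahashi et al. (1982), then SWS -> total."""
    k = equilibrium_constants(temperature_c, salinity_psu)
    TK = temperature_c + 273.15
    fH = 1.2948 - 0.002036 * TK + (0.0004607 - 0.000001475 * TK) * salinity_psu ** 2
    h_sws = 10.0 ** (-ph_nbs) / fH
    h_tot = h_sws * k.sws_to_total
    return float(-np.log10(h_tot))


def _alk_parts(h_total: float, k: ConstantsSet) -> dict:
    """Non-carbonate alkalinity components at a given total-scale [H+]."""
    h_free = h_total / (1.0 + k.total_sulfate / k.KS)
    return {
        "OH": k.KW / h_total,
        "BOH4": k.total_borate * k.KB / (k.KB + h_total),
        "H_free": h_free,
        "HSO4": k.total_sulfate / (1.0 + k.KS / h_free),
        "HF": k.total_fluoride / (1.0 + k.KF / h_free),
    }


def solve_from_ph_ta(
    sample: WaterSample, constants: ConstantsSet | None = None
) -> CarbonateState:
    """Carbonate speciation from (pH_total, TA) at in-situ T, S.

    Carbonate alkalinity is TA minus the borate, water and minor acid-base
    contributions; HCO3/CO3 follow from it and K2, CO2(aq) from K1, pCO2
    from K0 (with the fugacity correction), and the saturation states from
    the calcium content and the Mucci solubility products.
    """
    k = constants or equilibrium_constants(sample.temperature_c, sample.salinity_psu)
    h = 10.0 ** (-sample.ph_total)
    ta = sample.ta_umol_kg * 1e-6
    parts = _alk_parts(h, k)
    ca_alk = ta - parts["BOH4"] - parts["OH"] + parts["H_free"] + parts["HSO4"] + parts["HF"]
    if ca_alk <= 0:
        raise ValueError(
            "carbonate alkalinity non-positive after borate/water correction: "
            "infeasible sample"
        )
    hco3 = ca_alk * h / (h + 2.0 * k.K2)
    co3 = ca_alk * k.K2 / (h + 2.0 * k.K2)
    co2aq = hco3 * h / k.K1
    dic = co2aq + hco3 + co3
    fco2 = co2aq / k.K0  # atm
    pco2 = fco2 / k.fugacity_factor
    return CarbonateState(
        DIC_umol_kg=dic * 1e6,
        pCO2_uatm=pco2 * 1e6,
        fCO2_uatm=fco2 * 1e6,
        CO3_umol_kg=co3 * 1e6,
        HCO3_umol_kg=hco3 * 1e6,
        CO2aq_umol_kg=co2aq * 1e6,
        omega_calcite=k.calcium * co3 / k.Ksp_calcite,
        omega_aragonite=k.calcium * co3 / k.Ksp_aragonite,
    )


def ph_from_dic_ta(
    dic_umol_kg: float,
    ta_umol_kg: float,
    temperature_c: float,
    salinity_psu: float,
) -> float:
    """Total-scale pH from (DIC, TA): root of the alkalinity balance in H.

    Safeguarded bracketing (Brent) on pH in (3, 12), tolerance 1e-12 in pH.
    Serves as the inverse of :func:`solve_from_ph_ta`.
    """
    if dic_umol_kg <= 0 or ta_umol_kg <= 0:
        raise ValueError("DIC and TA must be positive")
    k = equilibrium_constants(temperature_c, salinity_psu)
    dic = dic_umol_kg * 1e-6
    ta = ta_umol_kg * 1e-6

    def balance(ph: float) -> float:
        h = 10.0 ** (-ph)
        denom = h * h + k.K1 * h + k.K1 * k.K2
        hco3 = dic * k.K1 * h / denom
        co3 = dic * k.K1 * k.K2 / denom
        parts = _alk_parts(h, k)
        ta_calc = (
            hco3 + 2.0 * co3 + parts["BOH4"] + parts["OH"]
            - parts["H_free"] - parts["HSO4"] - parts["HF"]
        )
        return ta_calc - ta

    lo, hi = 3.0, 12.0
    if balance(lo) * balance(hi) > 0:
        raise ValueError("no root bracketed in pH (3, 12)")
    return float(brentq(balance, lo, hi, xtol=1e-12))
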