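"""Freshwater carbonate speciation and simple derived geochemistry.

Speciation follows the classical titration-alkalinity route: total
alkalinity (ALK), pH and water temperature fix the carbonate system once
the dissociation constants of carbonic acid are known.  K1 and K2 use the
Plummer & Busenberg (1982) temperature fits, Kw a standard freshwater fit,
and activity coefficients come from the Davies equation (adequate to
ionic strengths of about 0.5 M, far above any river water).  The
alkalinity model is carbonate + water alkalinity only — appropriate for
freshwater titrated with HCl, where borate/phosphate/silicate terms are
negligible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

#: atomic masses (g/mol) for unit conversion
ATOMIC_MASS = {"Ca": 40.078, "Sr": 87.62}

#: ion charges for ionic-strength computation (concentrations in mol/L)
ION_CHARGE = {"Na": 1, "K": 1, "Mg": 2, "Ca": 2, "Cl": -1, "SO4": -2,
              "NO3": -1, "HCO3": -1, "CO3": -2, "H": 1, "OH": -1, "Sr": 2}


def k1_carbonic(wt_c: float) -> float:
    """First dissociation constant of carbonic acid at temperature ``wt_c`` (C).

    Plummer & Busenberg (1982) fit, thermodynamic (infinite-dilution) scale.
    """
    T = wt_c + 273.15
    log10_k1 = (-356.3094 - 0.06091964 * T + 21834.37 / T
                + 126.8339 * np.log10(T) - 1684915.0 / T ** 2)
    return 10.0 ** log10_k1


def k2_carbonic(wt_c: float) -> float:
    """Second dissociation constant of carbonic acid (Plummer & Busenberg 1982)."""
    T = wt_c + 273.15
    log10_k2 = (-107.8871 - 0.03252849 * T + 5151.79 / T
                + 38.92561 * np.log10(T) - 563713.9 / T ** 2)
    return 10.0 ** log10_k2


def kw_water(wt_c: float) -> float:
    """Ion product of water, freshwater fit (Harned & Owen form)."""
    T = wt_c + 273.15
    log10_kw = -4470.99 / T + 6.0875 - 0.01706 * T
    return 10.0 ** log10_kw


def debye_huckel_a(wt_c: float) -> float:
    """Debye–Hückel A parameter (quadratic fit over 0–50 C)."""
    return 0.4918 + 5.56e-4 * wt_c + 5.6e-6 * wt_c ** 2


def davies_gamma(charge: int, ionic_strength: float, wt_c: float = 25.0) -> float:
    """Davies-equation activity coefficient for an ion of given charge."""
    if ionic_strength < 0:
        raise ValueError("ionic strength must be >= 0")
    if ionic_strength == 0 or charge == 0:
        return 1.0
    A = debye_huckel_a(wt_c)
    sqrt_i = np.sqrt(ionic_strength)
    log10_g = -A * charge ** 2 * (sqrt_i / (1 + sqrt_i) - 0.3 * ionic_strength)
    return 10.0 ** log10_g


def ionic_strength(ions_mol: Mapping[str, float]) -> float:
    """I = 1/2 sum c_i z_i^2 from a map of ion -> concentration (mol/L)."""
    total = 0.0
    for ion, conc in ions_mol.items():
        if ion not in ION_CHARGE:
            raise KeyError(f"unknown ion {ion!r}")
        if conc < 0:
            raise ValueError(f"negative concentration for {ion!r}")
        total += conc * ION_CHARGE[ion] ** 2
    return 0.5 * total


@dataclass
class CarbonateSpeciation:
    """Concentrations in mol/L plus the corrected (mixed) constants used."""

    CO2: float
    HCO3: float
    CO3: float
    DIC: float
    K1: float  # mixed constant: activity of H x concentration ratio
    K2: float
    ionic_strength: float

    def __post_init__(self) -> None:
        if min(self.CO2, self.HCO3, self.CO3) < 0:
            raise ValueError("negative carbonate species")
        if abs(self.DIC - (self.CO2 + self.HCO3 + self.CO3)) > 1e-12 * max(self.DIC, 1e-30):
            raise ValueError("DIC does not equal the sum of species")


def carbonate_speciation(
    alk: float,
    ph: float,
    wt: float,
    ions: Mapping[str, float] | None = None,
    ionic_strength_value: float | None = None,
) -> CarbonateSpeciation:
    """Solve the carbonate system from titration alkalinity, pH and temperature.

    Parameters
    ----------
    alk:
        Total alkalinity in mol/L (equivalents).
    ph:
        pH on the activity scale (a_H = 10^-pH).
    wt:
        Water temperature in degrees C (0–40).
    ions:
        Optional major-ion concentrations (mol/L) used to compute the ionic
        strength for the Davies correction; ``ionic_strength_value`` may be
        given directly instead.  With neither, infinite dilution is assumed.
    """
    if alk <= 0:
        raise ValueError("alkalinity must be positive")
    if not 0 < ph < 14:
        raise ValueError("pH outside (0, 14)")
    if not 0 <= wt <= 40:
        raise ValueError("temperature outside 0-40 C")
    if ionic_strength_value is not None:
        I = float(ionic_strength_value)
    elif ions is not None:
        I = ionic_strength(ions)
    else:
        I = 0.0

    g1 = davies_gamma(1, I, wt)
    g2 = davies_gamma(2, I, wt)
    a_h = 10.0 ** (-ph)
    k1, k2, kw = k1_carbonic(wt), k2_carbonic(wt), kw_water(wt)
    # mixed constants: thermodynamic K over activity coefficients, so that
    # K1' = a_H [HCO3]/[CO2] and K2' = a_H [CO3]/[HCO3]
    k1_mixed = k1 / g1          # CO2(aq) taken as ideal (gamma = 1)
    k2_mixed = k2 * g1 / g2
    h_conc = a_h / g1
    oh_conc = kw / (a_h * g1)

    carb_alk = alk - oh_conc + h_conc
    if carb_alk <= 0:
        raise ValueError("alkalinity inconsistent with pH: "
                         "carbonate alkalinity non-positive after OH/H correction")
    ratio = k2_mixed / a_h            # [CO3]/[HCO3]
    hco3 = carb_alk / (1 + 2 * ratio)
    co3 = ratio * hco3
    co2 = a_h * hco3 / k1_mixed
    dic = co2 + hco3 + co3
    return CarbonateSpeciation(CO2=co2, HCO3=hco3, CO3=co3, DIC=dic,
                               K1=k1_mixed, K2=k2_mixed, ionic_strength=I)


def din(no3_n: float, no2_n: float, nh4_n: float) -> float:
    """Dissolved inorganic nitrogen: the sum of NO3-N, NO2-N and NH4-N (umol/L)."""
    parts = (no3_n, no2_n, nh4_n)
    if any(v < 0 for v in parts):
        raise ValueError("DIN components must be non-negative")
    return float(sum(parts))


def ca_sr_molar_ratio(ca: float, sr: float, ca_unit: str = "umol/L",
                      sr_unit: str = "umol/L") -> float:
    """Molar Ca/Sr ratio with explicit unit tags (umol/L, mmol/L, mol/L, mg/L).

    Returns NaN when Sr is zero (undefined source signature).
    """
    def to_umol(value: float, unit: str, element: str) -> float:
        if unit == "umol/L":
            return value
        if unit == "mmol/L":
            return value * 1e3
        if unit == "mol/L":
            return value * 1e6
        if unit == "mg/L":
            return value / ATOMIC_MASS[element] * 1e3
        raise ValueError(f"unknown unit {unit!r}")

    ca_umol = to_umol(ca, ca_unit, "Ca")
    sr_umol = to_umol(sr, sr_unit, "Sr")
    if sr_umol == 0:
        return float("nan")
    if sr_umol < 0 or ca_umol < 0:
        raise ValueError("concentrations must be non-negative")
    return ca_umol / sr_umol
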