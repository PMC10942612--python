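"""Physical properties of water needed by respirometry and fluid-dynamic scaling.

All three quantities are evaluated from standard empirical correlations:

* dissolved-oxygen solubility at 100 % air saturation — Benson & Krause (1984)
  equation as adopted for the USGS DOTABLES service, with optional salinity and
  barometric-pressure corrections;
* density — Kell's polynomial for air-free water at 1 atm;
* dynamic viscosity — Vogel-type correlation ``A * 10**(B / (T - C))``.

These are closed forms, not fits performed here; they reproduce published
tables to well under 1 % over 0–40 °C.
"""

from __future__ import annotations

import math

__all__ = ["o2_solubility", "water_density", "water_viscosity"]


def o2_solubility(temp_c: float, salinity_psu: float = 0.0,
                  pressure_atm: float = 1.0) -> float:
    """O2 concentration (mg L-1) of air-saturated water.

    Parameters
    ----------
    temp_c : water temperature in deg C (0–40).
    salinity_psu : practical salinity (per-mille); 0 for fresh water.
    pressure_atm : barometric pressure in atm.

    Returns
    -------
    float
        Dissolved O2 at 100 % air saturation, mg O2 per litre.
    """
    if not (0.0 <= temp_c <= 40.0):
        raise ValueError(f"temperature {temp_c} degC outside 0-40 degC validity range")
    t_k = temp_c + 273.15
    # Benson & Krause (1984), baseline freshwater solubility at 1 atm.
    ln_c = (-139.34411
            + 1.575701e5 / t_k
            - 6.642308e7 / t_k ** 2
            + 1.2438e10 / t_k ** 3
            - 8.621949e11 / t_k ** 4)
    c0 = math.exp(ln_c)
    # Salinity correction.
    if salinity_psu:
        fs = math.exp(-salinity_psu * (0.017674 - 10.754 / t_k + 2140.7 / t_k ** 2))
        c0 *= fs
    # Pressure correction (vapour-pressure and second-virial terms).
    if pressure_atm != 1.0:
        ln_pwv = 11.8571 - 3840.70 / t_k - 216961.0 / t_k ** 2
        p_wv = math.exp(ln_pwv)  # atm
        theta = 0.000975 - 1.426e-5 * temp_c + 6.436e-8 * temp_c ** 2
        p = pressure_atm
        c0 *= p * (1.0 - p_wv / p) * (1.0 - theta * p) / ((1.0 - p_wv) * (1.0 - theta))
    return c0


def water_density(temp_c: float) -> float:
    """Density of air-free water at 1 atm (kg m-3), Kell (1975) polynomial."""
    t = temp_c
    num = (999.83952 + 16.945176 * t - 7.9870401e-3 * t ** 2
           - 46.170461e-6 * t ** 3 + 105.56302e-9 * t ** 4
           - 280.54253e-12 * t ** 5)
    return num / (1.0 + 16.897850e-3 * t)


def water_viscosity(temp_c: float) -> float:
    """Dynamic viscosity of water (Pa s); ~8.3e-4 at 28 degC."""
    t_k = temp_c + 273.15
    return 2.414e-5 * 10.0 ** (247.8 / (t_k - 140.0))
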