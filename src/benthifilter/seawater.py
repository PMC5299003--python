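"""Physical properties of brackish seawater needed for diffusive-flux work.

Only dynamic viscosity is required here: free-solution diffusion
coefficients are scaled between pure water and in-situ conditions through
the Stokes–Einstein proportionality D·μ/T = const.
"""

from __future__ import annotations

ATM_TO_BAR = 1.013253


def dynamic_viscosity(salinity: float, temperature: float, pressure_atm: float = 1.0) -> float:
    """Dynamic viscosity of (sea)water in centipoise.

    Polynomial fit of Kukulka et al. as adopted in early-diagenesis
    modelling practice; valid for 0–30 °C, 0–40 salinity and pressures up
    to a few hundred bar.

    Parameters
    ----------
    salinity : practical salinity (dimensionless, ~psu)
    temperature : in-situ temperature, °C
    pressure_atm : total pressure, atm
    """
    if not -2.0 <= temperature <= 40.0:
        raise ValueError(f"temperature {temperature} degC outside fit range (-2, 40)")
    if not 0.0 <= salinity <= 45.0:
        raise ValueError(f"salinity {salinity} outside fit range (0, 45)")
    if pressure_atm <= 0:
        raise ValueError("pressure must be positive")
    t = temperature
    s = salinity
    p = pressure_atm * ATM_TO_BAR  # bar
    mu = 1.7910 - t * (6.144e-2 - t * (1.4510e-3 - t * 1.6826e-5))
    mu += -1.5290e-4 * p + 8.3885e-8 * p * p
    mu += 2.4727e-3 * s
    mu += t * (6.0574e-6 * p - 2.6760e-9 * p * p)
    mu += s * (4.8429e-5 * t - 4.7172e-6 * t**2 + 7.5986e-8 * t**3)
    return mu
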