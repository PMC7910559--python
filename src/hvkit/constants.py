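"""Physical constants used throughout, in millivolt/millisecond units."""

import math

#: k_B/e0 = R/F in mV per kelvin
KB_OVER_E0_MV = 8.617333262e-2

#: Reference temperature (K). ln(10)*k_B*T/e0 evaluates to 58.9 mV/pH here,
#: the constant used for the perfect proton-selectivity reference line.
T_REF = 297.0

LN10 = math.log(10.0)


def thermal_voltage(T: float) -> float:
    """k_B*T/e0 in mV at absolute temperature ``T`` (K)."""
    if T <= 0:
        raise ValueError(f"absolute temperature must be positive, got {T}")
    return KB_OVER_E0_MV * T


def nernst_slope(T: float) -> float:
    """ln(10)*k_B*T/e0 in mV per pH unit (58.9 mV at 297 K)."""
    return LN10 * thermal_voltage(T)
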