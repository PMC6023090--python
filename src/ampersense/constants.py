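"""Physical constants and the closed-form electrochemical coefficients.

Internal unit convention throughout the package: ampere, volt, second,
centimetre, mol/cm^3.  This is the convention under which the familiar
Randles-Sevcik prefactor takes its textbook value 2.69e5 at 25 degC; all
user-facing I/O (uA, mV/s, mM) is converted at the boundary.
"""

import math

#: Faraday constant, C/mol
FARADAY = 96485.0

#: Universal gas constant, J/(mol K)
GAS_CONSTANT = 8.314

#: Standard laboratory temperature, K
T_STANDARD = 298.15


def randles_sevcik_coefficient(temperature: float = T_STANDARD) -> float:
    """Prefactor of the reversible peak-current relation.

    i_p = coeff * n^1.5 * D^0.5 * C * A * v^0.5  with D in cm^2/s, C in
    mol/cm^3, A in cm^2, v in V/s and i_p in A.  The coefficient is
    0.4463 * F^1.5 / (R*T)^0.5; at 298.15 K it evaluates to 2.69e5
    (three significant figures), the value quoted in every textbook.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return 0.4463 * FARADAY**1.5 / math.sqrt(GAS_CONSTANT * temperature)


def nernstian_slope(temperature: float = T_STANDARD, n: int = 1) -> float:
    """Nernstian slope ln(10)*R*T/(n*F) in volts per decade.

    59.16 mV/decade at 298.15 K for a one-electron couple; peak
    separations at or below this scale carry no kinetic information.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    if n < 1:
        raise ValueError(f"n must be a positive integer, got {n}")
    return math.log(10.0) * GAS_CONSTANT * temperature / (n * FARADAY)
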