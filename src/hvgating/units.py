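"""Physical constants and unit conversions.

Internal conventions: time in ms, voltage in mV, charge in elementary
charges (e0) or femtocoulombs, distance in Angstrom, energy in kcal/mol.
All constants are taken from :mod:`scipy.constants`; nothing thermal is
hard-coded.
"""

from scipy import constants as _c

#: Elementary charge in femtocoulombs (1 fC = 1e-15 C).
E0_FC = _c.elementary_charge * 1e15

#: Faraday constant, C/mol.
FARADAY = _c.physical_constants["Faraday constant"][0]

#: Molar gas constant, J/(mol K).
GAS_CONSTANT = _c.R

#: Joules per thermochemical kilocalorie.
J_PER_KCAL = _c.calorie * 1000.0

#: Coulomb constant in kcal Angstrom / (mol e0^2): e0^2 * N_A / (4 pi eps0 * 1 Angstrom),
#: expressed in kcal/mol.  Evaluates to ~332.06.
COULOMB_KCAL_A = (
    _c.elementary_charge**2
    * _c.Avogadro
    / (4.0 * _c.pi * _c.epsilon_0 * 1e-10)
    / J_PER_KCAL
)

#: Standard recording temperature, Kelvin (22 degrees C).
ROOM_TEMPERATURE_K = 295.15


def thermal_voltage_mv(temperature_k: float) -> float:
    """kT/e0 in millivolts at the given temperature.

    ~25.43 mV at 295.15 K.
    """
    if not temperature_k > 0:
        raise ValueError(f"temperature must be positive, got {temperature_k}")
    return _c.Boltzmann * temperature_k / _c.elementary_charge * 1e3
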