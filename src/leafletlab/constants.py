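"""Physical constants and unit conversions used throughout the package.

Internal unit system: lengths in Å, surface pressures and moduli in mN/m,
times in s, frequencies in Hz, electron densities in e⁻/Å³.
"""

#: Boltzmann constant, J/K.
K_B = 1.380649e-23

#: 1 mN/m · Å² expressed in joules (1e-3 N/m × 1e-20 m²).
MNM_A2_IN_J = 1.0e-23

#: Classical electron radius, Å.
R_E = 2.818e-5

#: Electron density of pure water, e⁻/Å³.
WATER_RHO_E = 0.334

#: Number density of bulk water, molecules/Å³.
WATER_NUMBER_DENSITY = 0.0334


def kT_mN_A2(temperature: float) -> float:
    """Thermal energy k_B·T in mN/m·Å² (the natural unit for π·A).

    At 293 K this is 404.5 mN/m·Å², so a 2D ideal gas at
    A = 40.45 Å²/molecule exerts π = 10 mN/m.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive (K)")
    return K_B * temperature / MNM_A2_IN_J


#: Electron counts per element for the species handled here.
ELECTRONS = {
    "H": 1,
    "C": 6,
    "N": 7,
    "O": 8,
    "P": 15,
    "S": 16,
}
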