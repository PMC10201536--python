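"""Physical constants and unit conversions.

Internal unit system: energy in eV, length in Angstrom, time in ps,
mass in amu, temperature in K, angles in degrees at module interfaces
(radians internally where noted).
"""

#: Boltzmann constant, eV / K (CODATA 2018).
KB_EV_PER_K = 8.617333262e-5

#: 1 eV expressed in the internal kinetic-energy unit amu * A^2 / ps^2.
#: 1 eV = 1.602176634e-19 J; 1 J = 6.0221407621e22 amu A^2 ps^-2.
EV_IN_AMU_A2_PS2 = 9648.53321233

#: 1 kJ mol^-1 nm^-1 expressed in eV / A (force unit conversion for
#: steering forces quoted in molecular-dynamics conventions).
KJ_PER_MOL_NM_IN_EV_PER_A = 1000.0 / 96485.33212331 / 10.0


def kinetic_temperature(kinetic_energy_ev: float, n_dof: int) -> float:
    """Instantaneous kinetic temperature (K) from total kinetic energy (eV)."""
    return 2.0 * kinetic_energy_ev / (n_dof * KB_EV_PER_K)
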