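"""Physical constants and unit conversions.

Unit conventions used throughout the package:

* model/user units: energies in eV, lengths in Angstrom, masses in amu;
* internal vibrational units: Hartree atomic units with mass-weighted
  normal coordinates Q in Bohr*sqrt(m_e);
* reported units: frequencies in cm^-1, energy changes in meV, orbital
  energy derivatives in meV per mass-weighted a.u.

All conversions go through the constants below (CODATA 2018); no other
module defines its own conversion factors.
"""

# energy
HARTREE_EV = 27.211386245988
EV_MEV = 1000.0

# length
BOHR_ANGSTROM = 0.529177210903

# mass: 1 amu in electron masses
AMU_ME = 1822.888486209

# Boltzmann constant in Hartree / K
KB_HARTREE = 3.166811563e-6

# angular frequency: 1 a.u. (Hartree/hbar) in cm^-1
AU_WAVENUMBER = 219474.6313632


def hessian_ev_ang_to_au(h):
    """Convert a force-constant matrix from eV/Angstrom^2 to Hartree/Bohr^2."""
    return h * (BOHR_ANGSTROM**2 / HARTREE_EV)


def omega_au_to_wavenumber(omega):
    """Convert a vibrational (angular) frequency from a.u. to cm^-1."""
    return omega * AU_WAVENUMBER


def wavenumber_to_omega_au(nu):
    """Convert a frequency in cm^-1 to atomic units."""
    return nu / AU_WAVENUMBER
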