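"""Normal-mode analysis of a Cartesian Hessian.

Mass-weighting, Eckart projection of rigid translations and rotations,
frequencies and orthonormal mass-weighted mode vectors.  Internal normal
coordinates are mass-weighted atomic units (Bohr * sqrt(m_e)); frequencies
are reported in cm^-1 with the a.u. values kept alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import (
    AMU_ME,
    BOHR_ANGSTROM,
    hessian_ev_ang_to_au,
    omega_au_to_wavenumber,
)
from .errors import ConfigError

__all__ = ["MolecularSystem", "NormalModeSet", "normal_mode_analysis", "displace_along_mode"]

#: threshold (cm^-1) below which a retained frequency is treated as
#: residual rigid-body / free-motion contamination in reports
NEAR_ZERO_CM = 10.0


@dataclass
class MolecularSystem:
    """Atoms, masses, Cartesian coordinates; the geometry Q is displaced from.

    Coordinates are Angstrom; the stored geometry defines the origin of the
    normal-coordinate expansion (Q_eq = 0).
    """

    symbols: list[str]
    masses: np.ndarray
    coordinates: np.ndarray
    charge: int = 0
    spin_multiplicity: int = 1
    comment: str = ""

    def __post_init__(self):
        self.masses = np.asarray(self.masses, dtype=float)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ConfigError("coordinates must have shape (n_atoms, 3)")
        if len(self.symbols) != len(self.masses) or len(self.masses) != len(self.coordinates):
            raise ConfigError("symbols, masses and coordinates disagree on atom count")
        if not np.all(np.isfinite(self.coordinates)):
            raise ConfigError("coordinates must be finite")
        if np.any(self.masses <= 0):
            raise ConfigError("masses must be positive")
        if self.spin_multiplicity < 1:
            raise ConfigError("spin multiplicity must be >= 1")

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    def displaced(self, delta: np.ndarray, comment: str = "") -> "MolecularSystem":
        return replace(self, coordinates=self.coordinates + delta, comment=comment)


@dataclass
class NormalModeSet:
    """Vibrational frequencies and orthonormal mass-weighted mode vectors.

    ``vectors[:, i]`` is mode i in mass-weighted Cartesian coordinates
    (dimensionless, orthonormal); ``frequencies_cm`` uses the negative-sign
    convention for imaginary modes.  ``n_projected`` rigid-body directions
    were removed before diagonalization, so n_modes + n_projected = 3N.
    """

    frequencies_cm: np.ndarray
    frequencies_au: np.ndarray
    vectors: np.ndarray
    reduced_masses: np.ndarray
    masses: np.ndarray
    n_projected: int
    linear: bool

    @property
    def n_modes(self) -> int:
        return len(self.frequencies_cm)

    @property
    def real_mode_indices(self) -> np.ndarray:
        """Modes with real, non-spurious frequencies (> NEAR_ZERO_CM)."""
        return np.flatnonzero(self.frequencies_cm > NEAR_ZERO_CM)

    def cartesian_displacement(self, mode_index: int, amount: float) -> np.ndarray:
        """Cartesian displacement (Angstrom, shape (n,3)) for a mass-weighted
        normal-coordinate displacement ``amount`` (a.u.) along one mode."""
        l = self.vectors[:, mode_index].reshape(-1, 3)
        m_e = (self.masses * AMU_ME)[:, None]
        return amount * l / np.sqrt(m_e) * BOHR_ANGSTROM

    def max_atom_displacement(self, mode_index: int, amount: float) -> float:
        """Largest single-atom Cartesian displacement (Angstrom)."""
        d = self.cartesian_displacement(mode_index, amount)
        return float(np.max(np.linalg.norm(d, axis=1)))


def _rigid_body_vectors(system: MolecularSystem, linear: bool | str = "auto"):
    """Orthonormal mass-weighted translation/rotation vectors at equilibrium."""
    n = system.n_atoms
    m = system.masses * AMU_ME
    sqrt_m = np.sqrt(m)
    coords = system.coordinates / BOHR_ANGSTROM
    com = (system.masses @ coords) / system.masses.sum()
    x = coords - com

    vecs = []
    for axis in range(3):
        t = np.zeros((n, 3))
        t[:, axis] = sqrt_m
        vecs.append(t.ravel())
    for axis in range(3):
        e = np.zeros(3)
        e[axis] = 1.0
        r = np.cross(x, np.broadcast_to(e, (n, 3)))
        vecs.append((sqrt_m[:, None] * r).ravel())

    basis = np.array(vecs).T  # (3n, 6)
    q, s, _ = np.linalg.svd(basis, full_matrices=False)
    # rank decides linearity: a linear molecule has only 2 rotations
    tol = s[0] * 1e-8
    rank = int(np.sum(s > tol))
    if linear == "auto":
        is_linear = rank == 5
    else:
        is_linear = bool(linear)
    keep = 5 if is_linear else 6
    if rank < keep:
        keep = rank
    return q[:, :keep], is_linear


def normal_mode_analysis(
    system: MolecularSystem,
    hessian: np.ndarray,
    hessian_units: str = "eV/angstrom^2",
    linear: bool | str = "auto",
    project_rotations: bool = True,
    symmetry_tol: float = 1e-6,
) -> NormalModeSet:
    """Diagonalize the mass-weighted, Eckart-projected Hessian.

    Parameters
    ----------
    hessian : (3N, 3N) Cartesian force-constant matrix; symmetrized on input,
        rejected if asymmetric beyond ``symmetry_tol`` (relative).
    hessian_units : "eV/angstrom^2" or "hartree/bohr^2".
    linear : True/False or "auto" (detected from the rank of the rigid-body
        space); decides whether 5 or 6 rigid-body modes are projected.
    project_rotations : if False only translations are projected (some
        quantum-chemistry Hessians are provided already rotation-projected).

    Frequencies are sorted ascending; imaginary eigenvalues are reported as
    negative cm^-1, never silently kept among the sampled modes.  Mode
    vector signs are fixed deterministically (largest-magnitude component
    positive).
    """
    n = system.n_atoms
    if n < 2:
        raise ConfigError("vibrational analysis needs at least 2 atoms")
    h = np.asarray(hessian, dtype=float)
    if h.shape != (3 * n, 3 * n):
        raise ConfigError(f"hessian shape {h.shape} incompatible with {n} atoms")
    scale = np.max(np.abs(h)) or 1.0
    if np.max(np.abs(h - h.T)) / scale > symmetry_tol:
        raise ConfigError("hessian asymmetric beyond tolerance")
    h = 0.5 * (h + h.T)

    if hessian_units == "eV/angstrom^2":
        h = hessian_ev_ang_to_au(h)
    elif hessian_units != "hartree/bohr^2":
        raise ConfigError(f"unknown hessian units {hessian_units!r}")

    m = np.repeat(system.masses * AMU_ME, 3)
    h_mw = h / np.sqrt(np.outer(m, m))

    rigid, is_linear = _rigid_body_vectors(system, linear)
    if not project_rotations:
        rigid = rigid[:, :3]
    n_proj = rigid.shape[1]

    # orthonormal basis of the internal (vibrational) complement
    proj = np.eye(3 * n) - rigid @ rigid.T
    q, s, _ = np.linalg.svd(proj)
    internal = q[:, : 3 * n - n_proj]

    evals, evecs = np.linalg.eigh(internal.T @ h_mw @ internal)
    vectors = internal @ evecs

    omega = np.sign(evals) * np.sqrt(np.abs(evals))
    order = np.argsort(omega)
    omega = omega[order]
    vectors = vectors[:, order]

    # deterministic sign: largest-magnitude component positive
    for i in range(vectors.shape[1]):
        j = np.argmax(np.abs(vectors[:, i]))
        if vectors[j, i] < 0:
            vectors[:, i] = -vectors[:, i]

    freq_cm = omega_au_to_wavenumber(omega)
    n_expected_zero = 0 if project_rotations else (5 if is_linear else 6) - 3
    n_near_zero = int(np.sum(np.abs(freq_cm) < NEAR_ZERO_CM))
    if n_near_zero > n_expected_zero:
        warnings.warn(
            f"{n_near_zero} near-zero frequencies retained after projection; "
            "Hessian may be ill-conditioned or the system has free internal "
            "motions (central-force transverse modes, internal rotors)",
            stacklevel=2,
        )

    # reduced mass per mode from the un-mass-weighted displacement pattern
    inv_mu = (vectors.reshape(n, 3, -1) ** 2 / system.masses[:, None, None]).sum(axis=(0, 1))
    reduced = 1.0 / inv_mu

    return NormalModeSet(
        frequencies_cm=freq_cm,
        frequencies_au=omega,
        vectors=vectors,
        reduced_masses=reduced,
        masses=system.masses.copy(),
        n_projected=n_proj,
        linear=is_linear,
    )


def displace_along_mode(
    system: MolecularSystem,
    modes: NormalModeSet,
    mode_index: int,
    amount: float,
) -> MolecularSystem:
    """Geometry displaced by ``amount`` (mass-weighted a.u.) along one mode.

    displace(+q) followed by displace(-q) recovers the input geometry to
    machine precision (the map is strictly linear).
    """
    if not np.isfinite(amount):
        raise ConfigError("displacement amount must be finite")
    delta = modes.cartesian_displacement(mode_index, amount)
    return system.displaced(delta, comment=f"mode {mode_index} q={amount:+.6g} mw-au")
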