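"""Huckel-Peierls (SSH-type) tight-binding backend.

A one-electron tight-binding model whose hopping integrals depend on bond
lengths, so electronic levels couple linearly (optionally quadratically) to
nuclear displacements.  It serves two purposes:

* an exact, analytically differentiable electronic-structure oracle for
  validating the finite-difference machinery of the coupling module, and
* a synthetic-fixture generator: geometry, Hessian, orbital energies,
  dipoles and excitation energies are all produced internally, so the whole
  diagnostic pipeline runs without any external quantum-chemistry engine.

Conventions: the Hamiltonian off-diagonal element for a bond is ``-t(r)``
with ``t > 0``, so the lowest orbital is the bonding combination (standard
Huckel usage).  Hoppings vary with bond length as

    t(r) = t0 - alpha_ep * (r - r_eq) - 1/2 * alpha_ep2 * (r - r_eq)^2

Exciton binding is a controlled mock: a scalar U subtracted from the
orbital-energy gap, either constant or ``U(r) = U0 * exp(-r / r0)`` on one
designated bond.  It exists to make the geometry dependence of the two-body
term switchable, not to model electron-electron interaction.

Units: energies eV, lengths Angstrom, masses amu (see :mod:`.constants`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .constants import BOHR_ANGSTROM
from .errors import (
    ConfigError,
    DegenerateGeometryError,
    DegenerateLevelError,
    InvalidStateError,
)

__all__ = [
    "BindingModel",
    "Excitation",
    "ElectronicResult",
    "TightBindingModel",
    "TightBindingBackend",
    "tb_solve",
    "tb_analytic_orbital_derivative",
    "tb_hessian",
    "linear_chain",
    "ring",
]


@dataclass(frozen=True)
class BindingModel:
    """Mock exciton-binding term subtracted from the orbital gap.

    kind:
        "none"     -> U = 0 (excitation energy == orbital gap exactly)
        "constant" -> U = u0 at every geometry
        "distance" -> U = u0 * exp(-r_bond / r0) on the designated bond
    """

    kind: str = "none"
    u0: float = 0.0
    r0: float = 1.0
    bond: tuple[int, int] | None = None

    def __post_init__(self):
        if self.kind not in ("none", "constant", "distance"):
            raise ConfigError(f"unknown binding model kind {self.kind!r}")
        if self.kind == "distance" and self.bond is None:
            raise ConfigError("distance-dependent binding requires a designated bond")
        if self.kind == "distance" and self.r0 <= 0:
            raise ConfigError("binding decay length r0 must be positive")

    def evaluate(self, positions: np.ndarray) -> float:
        """Binding energy U (eV) at the given site coordinates."""
        if self.kind == "none":
            return 0.0
        if self.kind == "constant":
            return self.u0
        a, b = self.bond
        r = float(np.linalg.norm(positions[b] - positions[a]))
        return self.u0 * np.exp(-r / self.r0)


@dataclass(frozen=True)
class Excitation:
    """Single-orbital-promotion excitation.

    ``pair`` is (occupied index, virtual index) into the orbital list;
    ``weight`` is the configuration weight of that pair (1.0 for a pure
    one-electron promotion).
    """

    energy: float
    pair: tuple[int, int]
    weight: float = 1.0


@dataclass
class ElectronicResult:
    """Outcome of one electronic-structure evaluation.

    ``energies`` are sorted ascending.  ``occupations`` are total electron
    counts per orbital; for open-shell systems the spin-resolved counts are
    also populated.  ``vectors[:, k]`` is the coefficient vector of orbital
    k, used for maximum-overlap tracking across displaced geometries.
    """

    energies: np.ndarray
    occupations: np.ndarray
    vectors: np.ndarray
    dipole: np.ndarray | None = None
    excitations: list[Excitation] = field(default_factory=list)
    occupations_alpha: np.ndarray | None = None
    occupations_beta: np.ndarray | None = None

    @property
    def n_orbitals(self) -> int:
        return len(self.energies)

    @property
    def n_electrons(self) -> int:
        return int(round(self.occupations.sum()))

    @property
    def open_shell(self) -> bool:
        return self.occupations_alpha is not None

    @property
    def homo_index(self) -> int:
        occ = np.flatnonzero(self.occupations > 0)
        if occ.size == 0:
            raise InvalidStateError("no occupied orbitals")
        return int(occ[-1])

    @property
    def lumo_index(self) -> int:
        idx = self.homo_index + 1
        if idx >= self.n_orbitals:
            raise InvalidStateError("no virtual orbital available")
        return idx

    @property
    def somo_index(self) -> int:
        """Highest singly occupied orbital (open-shell systems)."""
        if not self.open_shell:
            raise InvalidStateError("SOMO undefined for a closed-shell result")
        singly = np.flatnonzero(
            (self.occupations_alpha + self.occupations_beta > 0)
            & (self.occupations_alpha + self.occupations_beta < 2 - 1e-12)
        )
        if singly.size == 0:
            raise InvalidStateError("no singly occupied orbital")
        return int(singly[-1])

    def sumo_index(self, convention: str = "minority_spin") -> int:
        """Lowest unoccupied orbital of an open-shell result.

        convention "minority_spin": lowest orbital empty in the minority
        spin channel (this is the SOMO's own spatial orbital for a
        spin-restricted model).  convention "same_spin": lowest orbital
        empty in the majority channel, i.e. the level above the SOMO.
        """
        somo = self.somo_index
        if convention == "minority_spin":
            return somo
        if convention == "same_spin":
            if somo + 1 >= self.n_orbitals:
                raise InvalidStateError("no orbital above the SOMO")
            return somo + 1
        raise ConfigError(f"unknown SUMO convention {convention!r}")

    def gap(self) -> float:
        """Fundamental gap E_L - E_H (eV)."""
        return float(self.energies[self.lumo_index] - self.energies[self.homo_index])


def _as_bond_array(value, n_bonds, name) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full(n_bonds, float(arr))
    if arr.shape != (n_bonds,):
        raise ConfigError(f"{name} must be scalar or one value per bond")
    return arr


@dataclass
class TightBindingModel:
    """Specification of a Huckel-Peierls model.

    Parameters
    ----------
    site_energies : on-site energies (eV), one per site.
    positions : equilibrium site coordinates, shape (n, 3) Angstrom
        (1D input is embedded along x).
    masses : site masses (amu).
    bonds : list of (i, j) bonded pairs; no self-loops or duplicates.
    t0 : equilibrium hopping magnitude (eV), scalar or per bond; > 0.
    alpha_ep : Peierls electron-phonon coupling d|t|/dr (eV/Angstrom).
    alpha_ep2 : quadratic hopping coefficient (eV/Angstrom^2); default 0.
    springs : harmonic bond force constants (eV/Angstrom^2); > 0.
    n_electrons : electron count; defaults to one per site (half filling).
    site_charges : nuclear-frame charges used by the mock dipole; default
        neutral (n_electrons / n_sites per site).
    binding : mock exciton-binding term, see :class:`BindingModel`.
    s1_pair : (p, q) selects the designated S1 promotion HOMO-p -> LUMO+q;
        default (0, 0), the HOMO->LUMO transition.
    """

    site_energies: np.ndarray
    positions: np.ndarray
    masses: np.ndarray
    bonds: list[tuple[int, int]]
    t0: np.ndarray | float = 1.0
    alpha_ep: np.ndarray | float = 0.0
    alpha_ep2: np.ndarray | float = 0.0
    springs: np.ndarray | float = 10.0
    n_electrons: int | None = None
    site_charges: np.ndarray | None = None
    binding: BindingModel = field(default_factory=BindingModel)
    s1_pair: tuple[int, int] = (0, 0)
    symbols: list[str] | None = None

    def __post_init__(self):
        self.site_energies = np.asarray(self.site_energies, dtype=float)
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim == 1:
            pos = np.column_stack([pos, np.zeros_like(pos), np.zeros_like(pos)])
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ConfigError("positions must be (n,) or (n, 3)")
        self.positions = pos
        self.masses = np.asarray(self.masses, dtype=float)
        n = self.n_sites
        if not (len(self.masses) == len(pos) == n):
            raise ConfigError("site_energies, positions and masses disagree on n_sites")
        if np.any(self.masses <= 0):
            raise ConfigError("all masses must be positive")
        seen = set()
        for a, b in self.bonds:
            if a == b:
                raise ConfigError(f"self-loop bond ({a}, {a})")
            if not (0 <= a < n and 0 <= b < n):
                raise ConfigError(f"bond ({a}, {b}) out of range")
            key = (min(a, b), max(a, b))
            if key in seen:
                raise ConfigError(f"duplicate bond {key}")
            seen.add(key)
        nb = len(self.bonds)
        self.t0 = _as_bond_array(self.t0, nb, "t0")
        self.alpha_ep = _as_bond_array(self.alpha_ep, nb, "alpha_ep")
        self.alpha_ep2 = _as_bond_array(self.alpha_ep2, nb, "alpha_ep2")
        self.springs = _as_bond_array(self.springs, nb, "springs")
        if np.any(self.t0 <= 0):
            raise ConfigError("equilibrium hoppings t0 must be positive")
        if np.any(self.springs <= 0):
            raise ConfigError("spring constants must be positive")
        if self.n_electrons is None:
            self.n_electrons = n
        if self.n_electrons < 0 or self.n_electrons > 2 * n:
            raise InvalidStateError(
                f"{self.n_electrons} electrons cannot occupy {n} sites (max {2 * n})"
            )
        if self.site_charges is None:
            self.site_charges = np.full(n, self.n_electrons / n)
        else:
            self.site_charges = np.asarray(self.site_charges, dtype=float)
        if self.symbols is None:
            self.symbols = ["C"] * n

    @property
    def n_sites(self) -> int:
        return len(self.site_energies)

    def bond_lengths(self, positions: np.ndarray | None = None) -> np.ndarray:
        pos = self.positions if positions is None else np.asarray(positions, float)
        return np.array(
            [np.linalg.norm(pos[b] - pos[a]) for a, b in self.bonds]
        )

    @property
    def equilibrium_bond_lengths(self) -> np.ndarray:
        return self.bond_lengths(self.positions)

    def with_binding(self, binding: BindingModel) -> "TightBindingModel":
        return replace(self, binding=binding)

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "site_energies": self.site_energies.tolist(),
            "positions": self.positions.tolist(),
            "masses": self.masses.tolist(),
            "bonds": [list(b) for b in self.bonds],
            "t0": self.t0.tolist(),
            "alpha_ep": self.alpha_ep.tolist(),
            "alpha_ep2": self.alpha_ep2.tolist(),
            "springs": self.springs.tolist(),
            "n_electrons": int(self.n_electrons),
            "site_charges": self.site_charges.tolist(),
            "s1_pair": list(self.s1_pair),
            "symbols": list(self.symbols),
            "binding": {
                "kind": self.binding.kind,
                "u0": self.binding.u0,
                "r0": self.binding.r0,
                "bond": list(self.binding.bond) if self.binding.bond else None,
            },
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TightBindingModel":
        d = dict(d)
        b = d.pop("binding", None)
        binding = BindingModel()
        if b:
            bond = b.get("bond")
            binding = BindingModel(
                kind=b.get("kind", "none"),
                u0=float(b.get("u0", 0.0)),
                r0=float(b.get("r0", 1.0)),
                bond=tuple(bond) if bond else None,
            )
        bonds = [tuple(int(x) for x in bb) for bb in d.pop("bonds")]
        s1 = tuple(int(x) for x in d.pop("s1_pair", (0, 0)))
        return cls(bonds=bonds, binding=binding, s1_pair=s1, **d)

    @classmethod
    def from_file(cls, path) -> "TightBindingModel":
        """Read a model specification from a YAML key/value file."""
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ConfigError(f"{path}: model spec must be a mapping")
        try:
            return cls.from_dict(d)
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"{path}: invalid model spec ({exc})") from exc

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# solver


def _hoppings(model: TightBindingModel, positions: np.ndarray) -> np.ndarray:
    r = model.bond_lengths(positions)
    if np.any(r <= 1e-8):
        raise DegenerateGeometryError("non-positive bond length: sites coincide")
    dr = r - model.equilibrium_bond_lengths
    return model.t0 - model.alpha_ep * dr - 0.5 * model.alpha_ep2 * dr**2


def _hamiltonian(model: TightBindingModel, positions: np.ndarray) -> np.ndarray:
    h = np.diag(model.site_energies.astype(float))
    t = _hoppings(model, positions)
    for (a, b), tb in zip(model.bonds, t):
        h[a, b] -= tb
        h[b, a] -= tb
    return h


def _occupy(n_orb: int, n_el: int):
    """Aufbau occupations; returns (total, alpha, beta) with beta None if closed."""
    if n_el > 2 * n_orb:
        raise InvalidStateError(f"{n_el} electrons exceed capacity {2 * n_orb}")
    occ = np.zeros(n_orb)
    n_pairs, odd = divmod(n_el, 2)
    occ[:n_pairs] = 2.0
    if odd:
        occ[n_pairs] = 1.0
        alpha = np.zeros(n_orb)
        alpha[: n_pairs + 1] = 1.0
        beta = np.zeros(n_orb)
        beta[:n_pairs] = 1.0
        return occ, alpha, beta
    return occ, None, None


def tb_solve(model: TightBindingModel, positions: np.ndarray | None = None) -> ElectronicResult:
    """Diagonalize the one-electron Hamiltonian at the given site coordinates.

    Returns sorted orbital energies, aufbau occupations, orbital vectors, the
    mock dipole (a.u., from nuclear-frame charges minus occupied-orbital site
    populations), and the excitation list dictated by the binding model.
    """
    pos = model.positions if positions is None else np.asarray(positions, float)
    if pos.shape != model.positions.shape:
        raise ConfigError(
            f"positions shape {pos.shape} does not match model {model.positions.shape}"
        )
    h = _hamiltonian(model, pos)
    energies, vectors = np.linalg.eigh(h)
    occ, occ_a, occ_b = _occupy(model.n_sites, model.n_electrons)

    # mock dipole: point charges (site_charge - electron population) at sites
    pops = (vectors**2) @ occ
    charges = model.site_charges - pops
    dipole = (charges @ pos) / BOHR_ANGSTROM  # e * Bohr

    result = ElectronicResult(
        energies=energies,
        occupations=occ,
        vectors=vectors,
        dipole=dipole,
        occupations_alpha=occ_a,
        occupations_beta=occ_b,
    )
    result.excitations = _excitations(model, pos, result)
    return result


def _excitations(model, positions, result) -> list[Excitation]:
    if result.n_electrons == 0 or result.n_electrons == 2 * result.n_orbitals:
        return []
    u = model.binding.evaluate(positions)
    exc = []
    if result.open_shell:
        somo = result.somo_index
        if somo + 1 < result.n_orbitals:
            e = result.energies[somo + 1] - result.energies[somo] - u
            exc.append(Excitation(float(e), (somo, somo + 1)))
        return exc
    homo, lumo = result.homo_index, result.lumo_index
    p, q = model.s1_pair
    occ_idx = homo - p
    virt_idx = lumo + q
    if occ_idx < 0 or virt_idx >= result.n_orbitals:
        raise ConfigError(f"s1_pair {model.s1_pair} outside the orbital space")
    e_s1 = result.energies[virt_idx] - result.energies[occ_idx] - u
    exc.append(Excitation(float(e_s1), (occ_idx, virt_idx)))
    # a few further single promotions near the frontier, gap minus the same U
    for i in range(max(0, homo - 2), homo + 1):
        for a in range(lumo, min(result.n_orbitals, lumo + 3)):
            if (i, a) == (occ_idx, virt_idx):
                continue
            e = result.energies[a] - result.energies[i] - u
            exc.append(Excitation(float(e), (i, a)))
    exc[1:] = sorted(exc[1:], key=lambda x: x.energy)
    return exc


def tb_analytic_orbital_derivative(
    model: TightBindingModel,
    positions: np.ndarray | None,
    orbital_index: int,
    direction: np.ndarray,
    degeneracy_tol: float = 1e-8,
) -> float:
    """Hellmann-Feynman derivative of one orbital energy (eV per unit step).

    ``direction`` is a Cartesian displacement pattern of shape (n_sites, 3)
    in Angstrom per unit step; the returned value is d eps_k / d lambda for
    positions + lambda * direction at lambda = 0.

    Requires the level to be isolated: a neighbour within ``degeneracy_tol``
    (eV) raises :class:`DegenerateLevelError` (use a degenerate-subspace
    treatment in that case).
    """
    pos = model.positions if positions is None else np.asarray(positions, float)
    direction = np.asarray(direction, dtype=float).reshape(pos.shape)
    res = tb_solve(model, pos)
    e = res.energies
    k = orbital_index
    gaps = []
    if k > 0:
        gaps.append(e[k] - e[k - 1])
    if k < len(e) - 1:
        gaps.append(e[k + 1] - e[k])
    if gaps and min(gaps) < degeneracy_tol:
        raise DegenerateLevelError(
            f"orbital {k} degenerate within {degeneracy_tol} eV of a neighbour; "
            "Hellmann-Feynman derivative undefined, use a subspace treatment"
        )
    r = model.bond_lengths(pos)
    dr_eq = r - model.equilibrium_bond_lengths
    dh = np.zeros((model.n_sites, model.n_sites))
    for bi, (a, b) in enumerate(model.bonds):
        ehat = (pos[b] - pos[a]) / r[bi]
        drdl = float(ehat @ (direction[b] - direction[a]))
        dtdl = (-model.alpha_ep[bi] - model.alpha_ep2[bi] * dr_eq[bi]) * drdl
        dh[a, b] -= dtdl
        dh[b, a] -= dtdl
    v = res.vectors[:, k]
    return float(v @ dh @ v)


def tb_hessian(model: TightBindingModel) -> np.ndarray:
    """Cartesian force-constant matrix (eV/Angstrom^2), shape (3n, 3n).

    Harmonic central-force springs on every bond, evaluated at the model's
    equilibrium geometry where all bond tensions vanish; rigid translations
    (and rotations) are therefore in the null space.
    """
    n = model.n_sites
    h = np.zeros((3 * n, 3 * n))
    r = model.equilibrium_bond_lengths
    for bi, (a, b) in enumerate(model.bonds):
        ehat = (model.positions[b] - model.positions[a]) / r[bi]
        block = model.springs[bi] * np.outer(ehat, ehat)
        sa, sb = slice(3 * a, 3 * a + 3), slice(3 * b, 3 * b + 3)
        h[sa, sa] += block
        h[sb, sb] += block
        h[sa, sb] -= block
        h[sb, sa] -= block
    return h


# ---------------------------------------------------------------------------
# backend adapter


class TightBindingBackend:
    """Backend-contract adapter around a :class:`TightBindingModel`.

    capabilities: ground_state, dipole, excited_states.  ``evaluate`` maps a
    molecular geometry (Angstrom site coordinates) to an
    :class:`ElectronicResult`; evaluation is deterministic.
    """

    capabilities = frozenset({"ground_state", "dipole", "excited_states"})

    def __init__(self, model: TightBindingModel):
        self.model = model

    def evaluate(self, system) -> ElectronicResult:
        coords = np.asarray(getattr(system, "coordinates", system), dtype=float)
        return tb_solve(self.model, coords)

    def system(self):
        """Equilibrium geometry as a :class:`~modecouple.vibrations.MolecularSystem`."""
        from .vibrations import MolecularSystem

        spin = 2 if self.model.n_electrons % 2 else 1
        return MolecularSystem(
            symbols=list(self.model.symbols),
            masses=self.model.masses.copy(),
            coordinates=self.model.positions.copy(),
            charge=0,
            spin_multiplicity=spin,
        )

    def hessian(self) -> np.ndarray:
        return tb_hessian(self.model)


# ---------------------------------------------------------------------------
# convenience builders


def linear_chain(
    n_sites: int,
    bond_length: float = 1.4,
    dimerization: float = 0.0,
    t0: float = 2.5,
    alpha_ep: float = 4.0,
    alpha_ep2: float = 0.0,
    spring: float = 30.0,
    mass: float = 12.011,
    site_energy: float = 0.0,
    n_electrons: int | None = None,
    **kwargs,
) -> TightBindingModel:
    """Open chain along x with optional Peierls dimerization.

    ``dimerization`` alternates bond lengths as r0 -/+ delta (short, long,
    short, ...), the classic SSH pattern.
    """
    lengths = [
        bond_length - dimerization * (1 if i % 2 == 0 else -1)
        for i in range(n_sites - 1)
    ]
    x = np.concatenate([[0.0], np.cumsum(lengths)])
    positions = np.column_stack([x, np.zeros(n_sites), np.zeros(n_sites)])
    return TightBindingModel(
        site_energies=np.full(n_sites, site_energy),
        positions=positions,
        masses=np.full(n_sites, mass),
        bonds=[(i, i + 1) for i in range(n_sites - 1)],
        t0=t0,
        alpha_ep=alpha_ep,
        alpha_ep2=alpha_ep2,
        springs=spring,
        n_electrons=n_electrons,
        **kwargs,
    )


def ring(
    n_sites: int,
    bond_length: float = 1.4,
    t0: float = 2.5,
    alpha_ep: float = 4.0,
    spring: float = 30.0,
    mass: float = 12.011,
    site_energy: float = 0.0,
    n_electrons: int | None = None,
    **kwargs,
) -> TightBindingModel:
    """Regular n-membered ring in the xy plane (benzene-like for n = 6)."""
    radius = bond_length / (2.0 * np.sin(np.pi / n_sites))
    theta = 2.0 * np.pi * np.arange(n_sites) / n_sites
    positions = np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), np.zeros(n_sites)]
    )
    bonds = [(i, (i + 1) % n_sites) for i in range(n_sites)]
    return TightBindingModel(
        site_energies=np.full(n_sites, site_energy),
        positions=positions,
        masses=np.full(n_sites, mass),
        bonds=bonds,
        t0=t0,
        alpha_ep=alpha_ep,
        springs=spring,
        n_electrons=n_electrons,
        **kwargs,
    )
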