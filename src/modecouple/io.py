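"""File I/O: XYZ geometries, plain-text Hessians, run configuration.

XYZ follows the standard convention — atom-count line, free-form comment
line, then ``element x y z`` rows in Angstrom — with multi-frame files being
simple concatenations.  Per-frame comments carry the mode/sign/sigma or
Monte Carlo sample metadata written by the thermal module.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError, ParseError
from .vibrations import MolecularSystem

__all__ = [
    "ATOMIC_MASSES",
    "read_xyz",
    "read_xyz_frames",
    "write_xyz",
    "read_hessian",
    "write_hessian",
    "RunConfig",
]

# standard atomic weights (amu) for the elements a fixture is likely to use
ATOMIC_MASSES = {
    "H": 1.008, "D": 2.014, "He": 4.002602,
    "Li": 6.94, "Be": 9.0121831, "B": 10.81, "C": 12.011, "N": 14.007,
    "O": 15.999, "F": 18.998403163, "Ne": 20.1797,
    "Na": 22.98976928, "Mg": 24.305, "Al": 26.9815385, "Si": 28.085,
    "P": 30.973761998, "S": 32.06, "Cl": 35.45, "Ar": 39.948,
    "K": 39.0983, "Ca": 40.078, "Fe": 55.845, "Zn": 65.38, "Br": 79.904,
    "I": 126.90447,
}


def _normalize_symbol(sym: str) -> str:
    return sym[:1].upper() + sym[1:].lower()


def _parse_frame(lines, start):
    """Parse one XYZ frame starting at ``lines[start]``; returns (system, next)."""
    try:
        n = int(lines[start].split()[0])
    except (ValueError, IndexError):
        raise ParseError("expected an atom count", line=start + 1)
    if n < 1:
        raise ParseError("atom count must be positive", line=start + 1)
    if start + 1 + n >= len(lines) + 1 and len(lines) < start + 2 + n:
        raise ParseError(f"truncated frame: {n} atoms declared", line=start + 1)
    comment = lines[start + 1].rstrip("\n")
    symbols, masses, coords = [], [], []
    for k in range(n):
        ln = start + 2 + k
        parts = lines[ln].split()
        if len(parts) < 4:
            raise ParseError("expected 'element x y z'", line=ln + 1)
        sym = _normalize_symbol(parts[0])
        if sym not in ATOMIC_MASSES:
            raise ParseError(f"unknown element {parts[0]!r}", line=ln + 1)
        try:
            xyz = [float(v) for v in parts[1:4]]
        except ValueError:
            raise ParseError("non-numeric coordinate", line=ln + 1)
        symbols.append(sym)
        masses.append(ATOMIC_MASSES[sym])
        coords.append(xyz)
    system = MolecularSystem(
        symbols=symbols,
        masses=np.array(masses),
        coordinates=np.array(coords),
        comment=comment,
    )
    return system, start + 2 + n


def read_xyz_frames(path) -> list[MolecularSystem]:
    """Read all frames of a (possibly multi-frame) XYZ file."""
    lines = Path(path).read_text().splitlines()
    frames = []
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        if pos + 1 >= len(lines):
            raise ParseError("truncated frame header", line=pos + 1)
        system, pos = _parse_frame(lines, pos)
        frames.append(system)
    if not frames:
        raise ParseError(f"{path}: no frames found")
    return frames


def read_xyz(path) -> MolecularSystem:
    """Read the first (usually only) frame of an XYZ file."""
    return read_xyz_frames(path)[0]


def write_xyz(systems, path) -> None:
    """Write a MolecularSystem, or a sequence of them, as (multi-frame) XYZ.

    Coordinates are printed with enough digits that read(write(x))
    round-trips well below 1e-10 Angstrom.
    """
    if isinstance(systems, MolecularSystem):
        systems = [systems]
    with open(path, "w") as fh:
        for s in systems:
            fh.write(f"{s.n_atoms}\n{s.comment}\n")
            for sym, (x, y, z) in zip(s.symbols, s.coordinates):
                fh.write(f"{sym:<3s} {x:20.12f} {y:20.12f} {z:20.12f}\n")


def read_hessian(path, n_atoms: int | None = None) -> np.ndarray:
    """Read a plain-text Cartesian Hessian.

    Two layouts are accepted:

    * dense: 3N rows of 3N whitespace-separated numbers (comment lines
      starting with '#' ignored), possibly wrapped over several lines;
    * lower-triangular packed (the common quantum-chemistry archive
      layout): the 3N(3N+1)/2 elements of the lower triangle in row-major
      order, any number of values per line.

    The layout is inferred from the element count; ``n_atoms`` resolves the
    (rare) ambiguity explicitly.
    """
    values = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        for tok in stripped.split():
            try:
                values.append(float(tok))
            except ValueError:
                raise ParseError(f"non-numeric entry {tok!r}", line=lineno)
    total = len(values)
    if n_atoms is not None:
        dim = 3 * n_atoms
        if total == dim * dim:
            return np.array(values).reshape(dim, dim)
        if total == dim * (dim + 1) // 2:
            return _unpack_lower(np.array(values), dim)
        raise ParseError(
            f"{path}: {total} values fit neither dense nor triangular "
            f"layout for {n_atoms} atoms"
        )
    dim = int(round(np.sqrt(total)))
    if dim * dim == total:
        return np.array(values).reshape(dim, dim)
    dim = int((np.sqrt(8 * total + 1) - 1) / 2)
    if dim * (dim + 1) // 2 == total:
        return _unpack_lower(np.array(values), dim)
    raise ParseError(f"{path}: {total} values fit no recognized Hessian layout")


def _unpack_lower(values, dim):
    h = np.zeros((dim, dim))
    idx = np.tril_indices(dim)
    h[idx] = values
    h = h + h.T - np.diag(np.diag(h))
    return h


def write_hessian(hessian, path, comment: str = "") -> None:
    """Write a dense plain-text Hessian."""
    h = np.asarray(hessian, dtype=float)
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        for row in h:
            fh.write(" ".join(f"{v: .16e}" for v in row) + "\n")


@dataclass
class RunConfig:
    """Everything a pipeline run needs, serializable to/from YAML.

    Exactly one of ``tb_model`` (path to a tight-binding model spec) or the
    ``geometry`` + ``hessian`` file pair must be provided.
    """

    tb_model: str | None = None
    geometry: str | None = None
    hessian: str | None = None
    hessian_units: str = "eV/angstrom^2"
    backend: str = "tb"
    temperature: float = 0.0
    step: float = 1e-3
    orbital_window: tuple[int, int] = (3, 1)
    degeneracy_tol_mev: float = 1.0
    strong_fraction: float = 0.2
    irav_gap_threshold: float | None = None
    irav_intensity_tol: float = 1e-6
    mc_samples: int = 0
    seed: int | None = None
    output_dir: str = "modecouple_out"
    verbosity: int = 1

    def validate(self) -> None:
        if self.tb_model is None and (self.geometry is None or self.hessian is None):
            raise ConfigError("config needs tb_model, or geometry + hessian")
        if self.tb_model is not None and self.geometry is not None:
            raise ConfigError("give either tb_model or geometry/hessian, not both")
        for name in ("step", "degeneracy_tol_mev", "strong_fraction", "irav_intensity_tol"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.temperature < 0:
            raise ConfigError("temperature must be >= 0")
        if self.mc_samples > 0 and self.seed is None:
            raise ConfigError("Monte Carlo sampling requires an explicit seed")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["orbital_window"] = list(self.orbital_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "orbital_window" in d:
            d["orbital_window"] = tuple(int(v) for v in d["orbital_window"])
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(d)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
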