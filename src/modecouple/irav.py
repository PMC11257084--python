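"""Infrared-active vibration (IRAV) analysis.

Per-mode IR intensities from dipole derivatives, a side-by-side
decomposition of orbital-energy derivatives over a window of orbitals below
and above the frontier, and flagging of IRAV candidates — including
symmetry-forbidden modes with no IR intensity but strong gap coupling,
which a computed IR spectrum alone would miss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coupling import (
    Backend,
    DEFAULT_STEP,
    ModeCouplingRecord,
    _require,
    orbital_energy_derivatives,
)
from .errors import ConfigError
from .vibrations import MolecularSystem, NormalModeSet, displace_along_mode

__all__ = [
    "IravRecord",
    "dipole_derivatives",
    "orbital_decomposition",
    "flag_iravs",
    "irav_analysis",
    "stick_spectrum",
]

#: |dD/dQ| (a.u. per mass-weighted a.u.) below which a mode counts as IR dark
DEFAULT_INTENSITY_TOL = 1e-6


@dataclass
class IravRecord:
    """One mode of the IRAV analysis.

    ``ir_intensity`` is |dD/dQ|^2 (proportional to the double-harmonic IR
    intensity); the raw derivative vector is kept alongside.  The
    per-orbital derivative table always includes the frontier pair.
    """

    mode_index: int
    frequency_cm: float
    dipole_derivative: np.ndarray
    dgap: float | None = None
    orbital_derivatives: dict[int, float] = field(default_factory=dict)
    orbital_derivatives_normalized: dict[int, float] = field(default_factory=dict)
    frontier: tuple[int, int] | None = None
    irav_candidate: bool = False
    ir_forbidden_irav: bool = False
    flags: list[str] = field(default_factory=list)

    @property
    def dipole_derivative_norm(self) -> float:
        return float(np.linalg.norm(self.dipole_derivative))

    @property
    def ir_intensity(self) -> float:
        return self.dipole_derivative_norm ** 2


def dipole_derivatives(
    backend: Backend,
    system: MolecularSystem,
    modes: NormalModeSet,
    step: float = DEFAULT_STEP,
    mode_indices=None,
) -> pd.DataFrame:
    """Central-finite-difference dipole derivative along each mode.

    Returns a DataFrame with the Cartesian components and the magnitude of
    dD/dQ_i (a.u. per mass-weighted a.u.).
    """
    _require(backend, "dipole")
    if mode_indices is None:
        mode_indices = modes.real_mode_indices
    rows = []
    for i in mode_indices:
        i = int(i)
        dp = backend.evaluate(displace_along_mode(system, modes, i, +step)).dipole
        dm = backend.evaluate(displace_along_mode(system, modes, i, -step)).dipole
        d = (np.asarray(dp) - np.asarray(dm)) / (2 * step)
        rows.append(
            {"mode": i, "freq_cm": modes.frequencies_cm[i],
             "dDx": d[0], "dDy": d[1], "dDz": d[2],
             "dD_norm": float(np.linalg.norm(d))}
        )
    return pd.DataFrame(rows)


def orbital_decomposition(
    backend: Backend,
    system: MolecularSystem,
    modes: NormalModeSet,
    window: tuple[int, int] = (3, 1),
    step: float = DEFAULT_STEP,
    mode_indices=None,
) -> pd.DataFrame:
    """Per-mode, per-orbital derivative table over a frontier window.

    ``window`` = (n below the highest occupied level, n above the lowest
    unoccupied level); it is truncated with a warning when it exceeds the
    orbital space.  A ``normalized`` column rescales each mode's column by
    the sum of absolute derivatives so relative orbital contributions are
    comparable across modes.
    """
    ref = backend.evaluate(system)
    lo_avail = ref.homo_index
    hi_avail = ref.n_orbitals - 1 - ref.lumo_index
    w = (min(window[0], lo_avail), min(window[1], hi_avail))
    if w != tuple(window):
        import warnings

        warnings.warn(
            f"orbital window {window} exceeds the orbital space; truncated to {w}",
            stacklevel=2,
        )
    table = orbital_energy_derivatives(
        backend, system, modes, orbital_window=w, step=step,
        mode_indices=mode_indices, reference=ref,
    )
    norm = table.groupby("mode")["derivative_mev_per_q"].transform(
        lambda c: c.abs().sum() or 1.0
    )
    table = table.assign(normalized=table["derivative_mev_per_q"] / norm)
    return table


def flag_iravs(
    records: list[IravRecord],
    gap_threshold: float | None = None,
    intensity_tolerance: float = DEFAULT_INTENSITY_TOL,
) -> list[IravRecord]:
    """Set irav_candidate / ir_forbidden_irav flags in place.

    ``irav_candidate``: |Delta E_gap| >= gap_threshold (meV; default 20% of
    the per-system maximum).  ``ir_forbidden_irav``: additionally
    |dD/dQ| <= intensity_tolerance — a symmetry-dark mode that is still
    strongly coupled to the electronic structure.  Flag logic is monotone in
    both thresholds.
    """
    gaps = np.array([abs(r.dgap) if r.dgap is not None else np.nan for r in records])
    if gap_threshold is None:
        max_gap = np.nanmax(gaps) if np.any(np.isfinite(gaps)) else 0.0
        gap_threshold = 0.2 * max_gap
    for r, g in zip(records, gaps):
        r.irav_candidate = bool(np.isfinite(g) and gap_threshold > 0 and g >= gap_threshold)
        r.ir_forbidden_irav = bool(
            r.irav_candidate and r.dipole_derivative_norm <= intensity_tolerance
        )
    return records


def irav_analysis(
    backend: Backend,
    system: MolecularSystem,
    modes: NormalModeSet,
    coupling_records: list[ModeCouplingRecord],
    window: tuple[int, int] = (3, 1),
    step: float = DEFAULT_STEP,
    gap_threshold: float | None = None,
    intensity_tolerance: float = DEFAULT_INTENSITY_TOL,
) -> list[IravRecord]:
    """Assemble IravRecords from dipole derivatives, the orbital
    decomposition and per-mode Delta E_gap, then apply the flag logic."""
    by_mode = {r.mode_index: r for r in coupling_records}
    mode_indices = sorted(by_mode)
    dips = dipole_derivatives(backend, system, modes, step, mode_indices)
    decomp = orbital_decomposition(backend, system, modes, window, step, mode_indices)
    records = []
    for _, row in dips.iterrows():
        i = int(row["mode"])
        cr = by_mode[i]
        sub = decomp[decomp["mode"] == i]
        rec = IravRecord(
            mode_index=i,
            frequency_cm=float(row["freq_cm"]),
            dipole_derivative=np.array([row["dDx"], row["dDy"], row["dDz"]]),
            dgap=cr.dgap,
            orbital_derivatives=dict(zip(sub["orbital"].astype(int),
                                         sub["derivative_mev_per_q"])),
            orbital_derivatives_normalized=dict(zip(sub["orbital"].astype(int),
                                                    sub["normalized"])),
            frontier=cr.frontier,
            flags=list(cr.flags),
        )
        records.append(rec)
    return flag_iravs(records, gap_threshold, intensity_tolerance)


def stick_spectrum(records: list[IravRecord]) -> pd.DataFrame:
    """Stick-spectrum table: frequency, intensity, gap coupling, flags."""
    return pd.DataFrame(
        [
            {
                "mode": r.mode_index,
                "freq_cm": r.frequency_cm,
                "ir_intensity_au": r.ir_intensity,
                "dD_norm_au": r.dipole_derivative_norm,
                "dEgap_mev": r.dgap,
                "irav_candidate": r.irav_candidate,
                "ir_forbidden_irav": r.ir_forbidden_irav,
            }
            for r in records
        ]
    )
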