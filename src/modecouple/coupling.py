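"""Mode-resolved electron-vibration coupling diagnostics.

Per-normal-mode derivatives of orbital energies, fundamental-gap changes
Delta E_gap at the characteristic +/-sigma_i(T) geometries, optical-gap
changes Delta E_S1 from excited-state evaluations, and the static binding
approximation (SBA) report comparing the two.

The bookkeeping identity

    Delta E_S1(Q) = Delta E_gap(Q) - Delta E_bind(Q)

holds exactly in every record where both quantities exist: the exciton
binding change is *defined* as the gap/optical-gap discrepancy.  The SBA is
the statement that Delta E_bind is negligible, so Delta E_gap — available
from ground-state orbital energies alone — diagnoses which vibrations
couple strongly to the optical transition.

Energies in records are meV; derivatives are meV per mass-weighted a.u.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Protocol

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .constants import EV_MEV
from .errors import CapabilityError, ComputationError, ConfigError
from .tb import ElectronicResult
from .thermal import thermal_factors
from .vibrations import MolecularSystem, NormalModeSet, displace_along_mode

__all__ = [
    "Backend",
    "TrackResult",
    "ModeCouplingRecord",
    "SbaReport",
    "track_orbitals",
    "orbital_energy_derivatives",
    "delta_gap",
    "delta_s1",
    "mode_coupling_analysis",
    "sba_report",
    "transition_gap_for_state",
    "open_shell_gap",
]

#: equilibrium frontier-orbital splitting (eV) below which the documented
#: SBA-overestimation flag for (near-)degenerate frontier orbitals is raised
DEGENERACY_TOL_EV = 1e-3

#: default finite-difference step, mass-weighted a.u.
DEFAULT_STEP = 1e-3


class Backend(Protocol):
    """Contract every electronic-structure backend must satisfy.

    ``capabilities`` declares which ElectronicResult fields ``evaluate``
    populates: "ground_state" (orbital energies + vectors), "dipole",
    "excited_states".  ``evaluate`` must be deterministic for identical
    input geometry.

    A reference adapter skeleton for an external quantum-chemistry engine::

        class MyQCBackend:
            capabilities = frozenset({"ground_state", "dipole"})

            def evaluate(self, system):
                # run the engine on system.coordinates (Angstrom), then
                # return ElectronicResult(energies_eV, occupations,
                #                         orbital_vectors, dipole_au)
                ...
    """

    capabilities: frozenset

    def evaluate(self, system: MolecularSystem) -> ElectronicResult: ...


def _require(backend, capability):
    if capability not in backend.capabilities:
        raise CapabilityError(f"backend lacks the {capability!r} capability")


# ---------------------------------------------------------------------------
# orbital tracking


@dataclass
class TrackResult:
    """Maximum-overlap orbital assignment between two geometries.

    ``permutation[k]`` is the displaced-geometry orbital corresponding to
    reference orbital k; ``overlaps[k]`` the matched |<ref_k|disp_perm[k]>|.
    """

    permutation: np.ndarray
    overlaps: np.ndarray
    ambiguous: np.ndarray  # boolean mask: matched overlap < 0.5

    def follow(self, k: int) -> int:
        return int(self.permutation[k])


def track_orbitals(reference: ElectronicResult, displaced: ElectronicResult) -> TrackResult:
    """Follow orbitals through level crossings by maximum overlap.

    Builds the |<ref_k|disp_l>| table (overlap in absolute value, so orbital
    phases are irrelevant) and solves the global assignment problem; the
    result is always a permutation.  Matches with best overlap below 0.5 are
    marked ambiguous.
    """
    if reference.vectors.shape != displaced.vectors.shape:
        raise ConfigError("orbital vector dimensions differ between results")
    ov = np.abs(reference.vectors.T @ displaced.vectors)
    rows, cols = linear_sum_assignment(-ov)
    perm = np.empty(reference.n_orbitals, dtype=int)
    perm[rows] = cols
    matched = ov[rows, perm[rows]]
    return TrackResult(permutation=perm, overlaps=matched, ambiguous=matched < 0.5)


# ---------------------------------------------------------------------------
# records


@dataclass
class ModeCouplingRecord:
    """Everything the diagnostic knows about one normal mode.

    Energy changes are meV, derivatives meV per mass-weighted a.u.
    ``dgap_plus``/``dgap_minus`` are the signed Delta E_gap at the +sigma and
    -sigma characteristic geometries; ``ds1_*`` and the derived ``dbind_*``
    are populated when the backend provides excited states.  The symmetric
    (odd, broadening) and asymmetric (even) parts of each +/- pair recombine
    exactly to the raw values: Delta(+/-) = asym +/- sym.
    """

    mode_index: int
    frequency_cm: float
    sigma: float
    d_homo: float | None = None
    d_lumo: float | None = None
    dgap_plus: float | None = None
    dgap_minus: float | None = None
    ds1_plus: float | None = None
    ds1_minus: float | None = None
    d_dipole: float | None = None
    orbital_derivatives: dict[int, float] = field(default_factory=dict)
    frontier: tuple[int, int] | None = None
    flags: list[str] = field(default_factory=list)

    # -- derived quantities -------------------------------------------

    @staticmethod
    def _mag(plus, minus):
        return max(abs(plus), abs(minus))

    @property
    def dgap(self) -> float | None:
        """Magnitude summary of the +/- pair: max(|Delta(+)|, |Delta(-)|)."""
        if self.dgap_plus is None:
            return None
        return self._mag(self.dgap_plus, self.dgap_minus)

    @property
    def dgap_symmetric(self) -> float | None:
        """Odd (broadening) part: (Delta(+) - Delta(-)) / 2."""
        if self.dgap_plus is None:
            return None
        return 0.5 * (self.dgap_plus - self.dgap_minus)

    @property
    def dgap_asymmetry(self) -> float | None:
        """Even part (Delta(+) + Delta(-)) / 2; zero for purely linear coupling."""
        if self.dgap_plus is None:
            return None
        return 0.5 * (self.dgap_plus + self.dgap_minus)

    @property
    def ds1(self) -> float | None:
        if self.ds1_plus is None:
            return None
        return self._mag(self.ds1_plus, self.ds1_minus)

    @property
    def dbind_plus(self) -> float | None:
        """Delta E_bind = Delta E_gap - Delta E_S1 (exact identity)."""
        if self.dgap_plus is None or self.ds1_plus is None:
            return None
        return self.dgap_plus - self.ds1_plus

    @property
    def dbind_minus(self) -> float | None:
        if self.dgap_minus is None or self.ds1_minus is None:
            return None
        return self.dgap_minus - self.ds1_minus

    def as_row(self) -> dict:
        row = {
            "mode": self.mode_index,
            "freq_cm": self.frequency_cm,
            "sigma_mwau": self.sigma,
            "dE_H_mev_per_q": self.d_homo,
            "dE_L_mev_per_q": self.d_lumo,
            "dEgap_plus_mev": self.dgap_plus,
            "dEgap_minus_mev": self.dgap_minus,
            "dEgap_mev": self.dgap,
            "dEgap_sym_mev": self.dgap_symmetric,
            "dEgap_asym_mev": self.dgap_asymmetry,
            "dES1_plus_mev": self.ds1_plus,
            "dES1_minus_mev": self.ds1_minus,
            "dES1_mev": self.ds1,
            "dEbind_plus_mev": self.dbind_plus,
            "dEbind_minus_mev": self.dbind_minus,
            "dD_dQ_au": self.d_dipole,
            "flags": ";".join(self.flags),
        }
        return row


# ---------------------------------------------------------------------------
# derivatives


def _window_indices(result: ElectronicResult, window: tuple[int, int], frontier: tuple[int, int]):
    lo = max(0, frontier[0] - window[0])
    hi = min(result.n_orbitals - 1, frontier[1] + window[1])
    return list(range(lo, hi + 1))


def orbital_energy_derivatives(
    backend: Backend,
    system: MolecularSystem,
    modes: NormalModeSet,
    orbital_window: tuple[int, int] = (3, 1),
    step: float = DEFAULT_STEP,
    mode_indices=None,
    reference: ElectronicResult | None = None,
) -> pd.DataFrame:
    """Central-finite-difference orbital energy derivatives per mode.

    For each mode the geometry is displaced by +/-``step`` (mass-weighted
    a.u.), the backend is evaluated, orbitals are tracked back to the
    equilibrium reference by maximum overlap, and the derivative
    (eps(+q) - eps(-q)) / (2 q) is formed.  The single equilibrium
    calculation is reused across all modes.

    Returns a tidy DataFrame with columns mode, orbital, derivative
    (meV per mass-weighted a.u.), overlap-ambiguity and failure flags.
    ``orbital_window`` = (n below HOMO, n above LUMO).
    """
    _require(backend, "ground_state")
    if step <= 0:
        raise ConfigError("finite-difference step must be positive")
    ref = backend.evaluate(system) if reference is None else reference
    frontier = (ref.homo_index, ref.lumo_index)
    orbitals = _window_indices(ref, orbital_window, frontier)
    if mode_indices is None:
        mode_indices = modes.real_mode_indices
    rows = []
    for i in mode_indices:
        i = int(i)
        try:
            res_p = backend.evaluate(displace_along_mode(system, modes, i, +step))
            res_m = backend.evaluate(displace_along_mode(system, modes, i, -step))
        except ComputationError as exc:
            for k in orbitals:
                rows.append(
                    {"mode": i, "orbital": k, "derivative_mev_per_q": np.nan,
                     "ambiguous": False, "failed": True, "error": str(exc)}
                )
            continue
        tp = track_orbitals(ref, res_p)
        tm = track_orbitals(ref, res_m)
        for k in orbitals:
            d = (res_p.energies[tp.follow(k)] - res_m.energies[tm.follow(k)]) / (2 * step)
            rows.append(
                {"mode": i, "orbital": k, "derivative_mev_per_q": d * EV_MEV,
                 "ambiguous": bool(tp.ambiguous[k] or tm.ambiguous[k]),
                 "failed": False, "error": ""}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Delta E at characteristic geometries


def _tracked_pair_gap(ref, disp, track, pair):
    i, a = pair
    return float(disp.energies[track.follow(a)] - disp.energies[track.follow(i)])


def _s1_energy(ref: ElectronicResult, disp: ElectronicResult, track: TrackResult,
               ref_pair: tuple[int, int]):
    """Excitation at the displaced geometry with the reference S1 character.

    The state is followed by its dominant orbital pair mapped through the
    orbital tracking, not by energy ordering; if no excitation with that
    character exists the lowest-energy one is used and flagged.
    """
    target = (track.follow(ref_pair[0]), track.follow(ref_pair[1]))
    for exc in disp.excitations:
        if tuple(exc.pair) == target:
            return exc.energy, False
    if not disp.excitations:
        raise ComputationError("backend returned no excitations")
    return min(disp.excitations, key=lambda x: x.energy).energy, True


def mode_coupling_analysis(
    backend: Backend,
    system: MolecularSystem,
    modes: NormalModeSet,
    temperature: float = 0.0,
    include_s1: bool = True,
    include_dipole: bool = True,
    include_derivatives: bool = True,
    orbital_window: tuple[int, int] = (3, 1),
    step: float = DEFAULT_STEP,
    mode_indices=None,
    frontier_pair: tuple[int, int] | None = None,
    state_pair: tuple[int, int] | None = None,
) -> list[ModeCouplingRecord]:
    """Full per-mode coupling analysis at the +/-sigma_i(T) geometries.

    For every real mode i the backend is evaluated at the two characteristic
    geometries displaced by +/-sigma_i(T); tracked frontier orbital energies
    give the signed Delta E_gap pair, and (when the backend has excited
    states and ``include_s1``) the character-tracked S1 energies give
    Delta E_S1.  Optionally the finite-difference orbital derivative table
    and dipole derivatives are attached.

    ``frontier_pair`` overrides the (HOMO, LUMO) pair, e.g. for SOMO/SUMO
    analyses; ``state_pair`` selects which reference excitation character is
    followed for Delta E_S1 (defaults to the backend's first excitation).
    """
    _require(backend, "ground_state")
    ref = backend.evaluate(system)
    if frontier_pair is None:
        frontier_pair = (ref.homo_index, ref.lumo_index)
    want_s1 = include_s1 and "excited_states" in backend.capabilities
    want_dip = include_dipole and "dipole" in backend.capabilities

    ref_pair = state_pair
    if want_s1 and ref_pair is None:
        if not ref.excitations:
            want_s1 = False
        else:
            ref_pair = tuple(ref.excitations[0].pair)
    e_gap0 = float(ref.energies[frontier_pair[1]] - ref.energies[frontier_pair[0]])
    e_s10 = None
    if want_s1:
        ident = TrackResult(np.arange(ref.n_orbitals), np.ones(ref.n_orbitals),
                            np.zeros(ref.n_orbitals, bool))
        e_s10, _ = _s1_energy(ref, ref, ident, ref_pair)

    degenerate = _frontier_degenerate(ref, frontier_pair)

    factors = thermal_factors(modes, temperature)
    if mode_indices is None:
        mode_indices = factors.mode_indices

    deriv_table = None
    if include_derivatives:
        deriv_table = orbital_energy_derivatives(
            backend, system, modes, orbital_window, step, mode_indices, reference=ref
        )

    records = []
    for i in mode_indices:
        i = int(i)
        sigma = factors.sigmas[i]
        rec = ModeCouplingRecord(
            mode_index=i,
            frequency_cm=float(modes.frequencies_cm[i]),
            sigma=float(sigma),
            frontier=frontier_pair,
        )
        if degenerate:
            rec.flags.append("degenerate_frontier_sba_overestimate")
        if not math.isfinite(sigma):
            rec.flags.append("no_thermal_sigma")
            records.append(rec)
            continue
        try:
            geo_p = displace_along_mode(system, modes, i, +sigma)
            geo_m = displace_along_mode(system, modes, i, -sigma)
            res_p = backend.evaluate(geo_p)
            res_m = backend.evaluate(geo_m)
        except ComputationError as exc:
            rec.flags.append(f"backend_failed:{exc}")
            records.append(rec)
            continue
        tp = track_orbitals(ref, res_p)
        tm = track_orbitals(ref, res_m)
        if tp.ambiguous[list(frontier_pair)].any() or tm.ambiguous[list(frontier_pair)].any():
            rec.flags.append("ambiguous_orbital_tracking")
        rec.dgap_plus = (_tracked_pair_gap(ref, res_p, tp, frontier_pair) - e_gap0) * EV_MEV
        rec.dgap_minus = (_tracked_pair_gap(ref, res_m, tm, frontier_pair) - e_gap0) * EV_MEV
        if want_s1:
            s1p, fb_p = _s1_energy(ref, res_p, tp, ref_pair)
            s1m, fb_m = _s1_energy(ref, res_m, tm, ref_pair)
            if fb_p or fb_m:
                rec.flags.append("s1_character_fallback_energy_order")
            rec.ds1_plus = (s1p - e_s10) * EV_MEV
            rec.ds1_minus = (s1m - e_s10) * EV_MEV
        if want_dip:
            dp = backend.evaluate(displace_along_mode(system, modes, i, +step)).dipole
            dm = backend.evaluate(displace_along_mode(system, modes, i, -step)).dipole
            rec.d_dipole = float(np.linalg.norm((dp - dm) / (2 * step)))
        if deriv_table is not None:
            sub = deriv_table[deriv_table["mode"] == i]
            rec.orbital_derivatives = dict(
                zip(sub["orbital"].astype(int), sub["derivative_mev_per_q"])
            )
            rec.d_homo = rec.orbital_derivatives.get(frontier_pair[0])
            rec.d_lumo = rec.orbital_derivatives.get(frontier_pair[1])
            if sub["ambiguous"].any():
                if "ambiguous_orbital_tracking" not in rec.flags:
                    rec.flags.append("ambiguous_orbital_tracking")
        records.append(rec)
    return records


def _frontier_degenerate(ref: ElectronicResult, pair, tol=DEGENERACY_TOL_EV) -> bool:
    """Near-degeneracy of either frontier orbital with any other level."""
    for k in pair:
        others = np.delete(ref.energies, k)
        if others.size and np.min(np.abs(others - ref.energies[k])) < tol:
            return True
    return False


def delta_gap(backend, system, modes, temperature=0.0, **kwargs) -> list[ModeCouplingRecord]:
    """Per-mode fundamental-gap change at the +/-sigma_i(T) geometries.

    Ground-state information only: this is the low-cost diagnostic.  See
    :func:`mode_coupling_analysis` for keyword options.
    """
    return mode_coupling_analysis(
        backend, system, modes, temperature, include_s1=False, **kwargs
    )


def delta_s1(backend, system, modes, temperature=0.0, state_pair=None, **kwargs):
    """Per-mode optical-gap change at the +/-sigma_i(T) geometries.

    Requires the excited_states capability; the S1 state is followed across
    geometries by its dominant orbital-pair character.
    """
    _require(backend, "excited_states")
    return mode_coupling_analysis(
        backend, system, modes, temperature, include_s1=True, state_pair=state_pair, **kwargs
    )


def transition_gap_for_state(
    backend, system, modes, equilibrium_excitation_index: int = 0,
    temperature: float = 0.0, **kwargs
) -> list[ModeCouplingRecord]:
    """Gap diagnostic for a transition that is not HOMO -> LUMO.

    One equilibrium excited-state calculation identifies the dominant
    occupied -> virtual pair of the requested state; the Delta E_gap
    machinery is then applied to that orbital pair.  A dominant weight
    below 0.5 is flagged multi-configurational (largest-weight pair used);
    a donor or acceptor level degenerate with a neighbour is flagged with
    the candidate pairs listed.
    """
    _require(backend, "excited_states")
    ref = backend.evaluate(system)
    if equilibrium_excitation_index >= len(ref.excitations):
        raise ConfigError(
            f"excitation index {equilibrium_excitation_index} out of range "
            f"({len(ref.excitations)} available)"
        )
    exc = ref.excitations[equilibrium_excitation_index]
    flags = []
    if exc.weight < 0.5:
        flags.append("multi_configurational_state")
    pair = tuple(exc.pair)
    candidates = [pair]
    for k in pair:
        dists = np.abs(ref.energies - ref.energies[k])
        dists[k] = np.inf
        if dists.min() < DEGENERACY_TOL_EV:
            if "degenerate_donor_acceptor" not in flags:
                flags.append("degenerate_donor_acceptor")
            # list the alternative pair built from the degenerate partner
            partner = int(np.argmin(dists))
            alt = (partner, pair[1]) if k == pair[0] else (pair[0], partner)
            candidates.append(alt)
    records = mode_coupling_analysis(
        backend, system, modes, temperature,
        include_s1=False, frontier_pair=pair, **kwargs
    )
    for rec in records:
        rec.flags.extend(flags)
        if len(candidates) > 1:
            rec.flags.append("candidate_pairs:" + ",".join(map(str, candidates)))
    return records


def open_shell_gap(
    backend, system, modes, temperature: float = 0.0,
    sumo_convention: str = "minority_spin", **kwargs
) -> list[ModeCouplingRecord]:
    """Fundamental-gap diagnostic for radicals with the (SOMO, SUMO) frontier.

    ``sumo_convention`` "minority_spin" takes the lowest orbital unoccupied
    in the minority spin channel (the SOMO's own spatial orbital for a
    spin-restricted backend, giving a zero gap); "same_spin" takes the level
    above the SOMO.  Closed-shell input raises, directing to delta_gap.
    """
    ref = backend.evaluate(system)
    if not ref.open_shell:
        raise ConfigError("closed-shell system: use delta_gap instead of open_shell_gap")
    pair = (ref.somo_index, ref.sumo_index(sumo_convention))
    return mode_coupling_analysis(
        backend, system, modes, temperature,
        include_s1=False, frontier_pair=pair, **kwargs
    )


# ---------------------------------------------------------------------------
# SBA report


@dataclass
class SbaReport:
    """Summary of the static-binding-approximation check.

    ``r_squared`` measures proximity of the (Delta E_gap, Delta E_S1) points
    to the identity diagonal — residuals are taken to y = x, not to a fitted
    line — using both signed +/- values per mode.  ``strong_modes`` are
    those with |Delta E_gap| at least ``strong_fraction`` of the per-system
    maximum.
    """

    table: pd.DataFrame
    r_squared: float | None
    ranked_modes: list[int]
    strong_modes: list[int]
    strong_fraction: float
    flags: list[str]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def sba_report(records: list[ModeCouplingRecord], strong_fraction: float = 0.2) -> SbaReport:
    """Build the per-mode SBA summary table and diagonal R-squared."""
    rows = [r.as_row() for r in records]
    table = pd.DataFrame(rows)
    flags = sorted({f for r in records for f in r.flags})

    gaps = np.array([r.dgap if r.dgap is not None else np.nan for r in records])
    order = np.argsort(-np.nan_to_num(np.abs(gaps), nan=-1.0))
    ranked = [records[i].mode_index for i in order if np.isfinite(gaps[i])]
    max_gap = np.nanmax(np.abs(gaps)) if np.any(np.isfinite(gaps)) else 0.0
    strong = [
        records[i].mode_index
        for i in range(len(records))
        if np.isfinite(gaps[i]) and max_gap > 0 and abs(gaps[i]) >= strong_fraction * max_gap
    ]

    xs, ys = [], []
    for r in records:
        if r.dgap_plus is not None and r.ds1_plus is not None:
            xs += [r.dgap_plus, r.dgap_minus]
            ys += [r.ds1_plus, r.ds1_minus]
    r2 = None
    if len(xs) >= 2:
        x = np.array(xs)
        y = np.array(ys)
        ss_res = float(np.sum((y - x) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        scale = max(np.max(np.abs(x)), np.max(np.abs(y)), 1e-300)
        if np.ptp(x) < 1e-12 * scale:
            # Delta E_gap carries no variance: nothing is "explained"
            r2 = 1.0 if ss_res <= (1e-12 * scale) ** 2 * len(x) else 0.0
            if r2 == 0.0:
                flags.append("degenerate_variance")
        elif ss_tot == 0.0:
            r2 = 1.0 if ss_res == 0.0 else 0.0
        else:
            r2 = 1.0 - ss_res / ss_tot
    return SbaReport(
        table=table,
        r_squared=r2,
        ranked_modes=ranked,
        strong_modes=strong,
        strong_fraction=strong_fraction,
        flags=flags,
    )
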