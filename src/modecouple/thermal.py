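"""Thermal population factors, characteristic +/-sigma geometries and
Monte Carlo geometry ensembles.

For a harmonic mode of frequency omega the coordinate distribution of the
quantum thermal state is Gaussian with variance

    sigma(T)^2 = coth(hbar*omega / (2 k_B T)) / (2 omega)      (mass-weighted a.u.)

The amplification factor p(T) = coth(.) = 1 + 2 n_BE(omega, T) equals unity
at T = 0, where sigma reduces to the zero-point width (2 omega)^(-1/2), and
grows monotonically with temperature; in the classical limit
hbar*omega << k_B T the variance approaches the equipartition value
k_B T / omega^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import KB_HARTREE
from .errors import ConfigError
from .vibrations import MolecularSystem, NormalModeSet, displace_along_mode

__all__ = [
    "ThermalFactors",
    "bose_population",
    "thermal_sigma",
    "thermal_factors",
    "characteristic_geometries",
    "monte_carlo_geometries",
]


def bose_population(frequency: float, temperature: float) -> float:
    """Thermal amplification factor p(T) = coth(hbar*omega/(2 k_B T)).

    ``frequency`` is omega in a.u. (Hartree), ``temperature`` in K.  The
    T -> 0 limit (p = 1) is taken analytically rather than through the
    overflow-prone coth evaluation.
    """
    omega = np.asarray(frequency, dtype=float)
    if np.any(omega <= 0):
        raise ConfigError("bose_population requires omega > 0")
    if temperature < 0:
        raise ConfigError("temperature must be >= 0")
    x = np.full_like(omega, np.inf)
    if temperature > 0:
        x = omega / (2.0 * KB_HARTREE * temperature)
    # coth(x) = 1 + 2/(e^{2x} - 1); exact 1.0 for x beyond double range
    with np.errstate(over="ignore"):
        p = np.where(x > 350.0, 1.0, 1.0 + 2.0 / np.expm1(np.minimum(2.0 * x, 1e308)))
    return float(p) if p.ndim == 0 else p


def thermal_sigma(frequency: float, temperature: float) -> float:
    """Standard deviation of the thermal coordinate distribution
    (mass-weighted a.u.): sigma = sqrt(p(T) / (2 omega))."""
    p = bose_population(frequency, temperature)
    return np.sqrt(p / (2.0 * np.asarray(frequency, dtype=float)))


@dataclass
class ThermalFactors:
    """Per-mode p_i(T) and sigma_i(T) at one temperature.

    Only modes with real frequencies above the near-zero threshold carry
    finite entries; excluded modes hold NaN.
    """

    temperature: float
    populations: np.ndarray
    sigmas: np.ndarray
    mode_indices: np.ndarray


def thermal_factors(modes: NormalModeSet, temperature: float) -> ThermalFactors:
    """Evaluate p_i(T) and sigma_i(T) for every real retained mode."""
    idx = modes.real_mode_indices
    p = np.full(modes.n_modes, np.nan)
    s = np.full(modes.n_modes, np.nan)
    if idx.size:
        omega = modes.frequencies_au[idx]
        p[idx] = bose_population(omega, temperature)
        s[idx] = thermal_sigma(omega, temperature)
    return ThermalFactors(temperature=float(temperature), populations=p, sigmas=s, mode_indices=idx)


def characteristic_geometries(
    system: MolecularSystem,
    modes: NormalModeSet,
    temperature: float = 0.0,
    mode_indices=None,
) -> list[tuple[int, int, float, MolecularSystem]]:
    """The two characteristic geometries +/- sigma_i(T) for each mode.

    Returns a list of (mode_index, sign, sigma, geometry).  Imaginary or
    near-zero modes are skipped with a warning; each +/- pair averages back
    to the equilibrium coordinates exactly.
    """
    factors = thermal_factors(modes, temperature)
    requested = modes.real_mode_indices if mode_indices is None else np.asarray(mode_indices)
    out = []
    for i in requested:
        if i not in factors.mode_indices:
            warnings.warn(
                f"mode {i} (freq {modes.frequencies_cm[i]:.1f} cm^-1) skipped: "
                "imaginary or near-zero frequency has no thermal sigma",
                stacklevel=2,
            )
            continue
        sigma = factors.sigmas[i]
        for sign in (+1, -1):
            geo = displace_along_mode(system, modes, int(i), sign * sigma)
            geo.comment = f"mode {i} sign {sign:+d} sigma {sigma:.8f} T {temperature:g}"
            out.append((int(i), sign, float(sigma), geo))
    return out


def monte_carlo_geometries(
    system: MolecularSystem,
    modes: NormalModeSet,
    temperature: float,
    n_samples: int,
    seed: int,
) -> list[MolecularSystem]:
    """Thermal geometry ensemble by independent Gaussian mode displacements.

    Each sample displaces every real mode by a zero-mean normal draw with
    standard deviation sigma_i(T); the same seed reproduces the ensemble
    bitwise.
    """
    if n_samples < 1:
        raise ConfigError("n_samples must be >= 1")
    if seed is None:
        raise ConfigError("a seed is required: no implicit randomness")
    rng = np.random.default_rng(seed)
    factors = thermal_factors(modes, temperature)
    idx = factors.mode_indices
    sigmas = factors.sigmas[idx]
    samples = []
    for s in range(n_samples):
        q = rng.normal(0.0, 1.0, size=idx.size) * sigmas
        delta = np.zeros_like(system.coordinates)
        for i, qi in zip(idx, q):
            delta += modes.cartesian_displacement(int(i), qi)
        geo = system.displaced(delta, comment=f"sample {s} seed {seed} T {temperature:g}")
        samples.append(geo)
    return samples
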