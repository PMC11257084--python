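# Methods

## Model and procedure

The diagnostic rests on three pieces.

**Normal-mode analysis.** A Cartesian force-constant matrix is symmetrized,
converted to atomic units, mass-weighted, and diagonalized in the
orthogonal complement of the rigid-body space. The rigid space is built
explicitly from mass-weighted translations and rotations at the reference
geometry (Eckart construction) and orthonormalized by SVD; its rank decides
whether the molecule is linear (5) or nonlinear (6). Diagonalizing in the
complement, rather than projecting and filtering near-zero eigenvalues,
guarantees the retained mode count is exactly 3N − 6 (or 3N − 5) and that
every mode satisfies the Eckart conditions to numerical precision.
Frequencies are reported in cm⁻¹; imaginary eigenvalues appear with a
negative sign and are excluded from thermal sampling, never silently kept.
Mode vectors are orthonormal in mass-weighted coordinates with a
deterministic sign convention (largest-magnitude component positive), so
repeated runs are byte-identical.

**Thermal widths.** For mode *i* the coordinate distribution of the quantum
harmonic thermal state is Gaussian with variance
σᵢ(T)² = pᵢ(T)/(2ωᵢ), where pᵢ(T) = coth(ħωᵢ/2k_BT) = 1 + 2n_BE is the
thermal amplification factor: unity at T = 0 (pure zero-point motion) and
approaching 2k_BT/ħωᵢ in the classical limit, where σ² → k_BT/ωᵢ².
The T → 0 branch is evaluated analytically rather than through coth, which
overflows. Characteristic geometries displace the equilibrium by ±σᵢ(T)
along one mode; Monte Carlo ensembles displace every real mode by an
independent zero-mean Gaussian of width σᵢ(T) (Gaussian, because σ is
defined as the standard deviation of that thermal distribution). Sampling
requires an explicit seed; there is no implicit randomness anywhere.

**Coupling diagnostics.** Orbital energy derivatives are central finite
differences (ε(+q) − ε(−q))/2q along each mode, with the single equilibrium
calculation reused. Orbitals are followed through level crossings by
maximum-overlap assignment: the |⟨ref|disp⟩| table is solved as a global
assignment problem (Hungarian algorithm), which always yields a
permutation; matches below 0.5 overlap are flagged ambiguous. ΔE_gap per
mode is evaluated at the two ±σᵢ(T) characteristic geometries with tracked
frontier orbitals (the derivative×σ estimate is available as a cheaper
alternative; evaluating at ±σ is the default because it is what the
excited-state comparison uses). ΔE_S1 follows the S1 state by its dominant
orbital-pair character mapped through the same tracking, not by energy
ordering, with an energy-ordered fallback that is flagged. The bookkeeping
identity ΔE_bind = ΔE_gap − ΔE_S1 is exact by construction wherever both
quantities exist.

Each ±σ pair is reduced to a magnitude max(|Δ(+σ)|, |Δ(−σ)|) for ranking
(the reduction to one number per mode is a reporting choice, so both signed
values and the odd/even decomposition are kept: Δ(±σ) = asym ± sym). The
even ("asymmetry") part vanishes identically when the level responds
linearly to the coordinate and is the first signature of anharmonic or
quadratic electron–phonon coupling.

The SBA report computes R² of the (ΔE_gap, ΔE_S1) scatter about the
identity line — residuals to y = x, not to a fitted regression line,
because the question is proximity to the diagonal, not linear correlation.
When ΔE_gap carries no variance the statistic is defined as 1 if the
residuals also vanish and 0 otherwise, with a degenerate-variance flag.

## The tight-binding backend

The Hückel–Peierls model is both the test oracle and the synthetic-data
generator. Sites carry on-site energies, masses and 3D positions; bonds
carry hoppings t(r) = t₀ − α(r − r_eq) − ½α₂(r − r_eq)² (off-diagonal
element −t, so the lowest orbital is bonding) and harmonic central-force
springs whose rest length is the reference bond length, making the
reference geometry tension-free and leaving translations and rotations
exactly in the Hessian null space. Hellmann–Feynman derivatives
⟨k|dH/dλ|k⟩ are available analytically for isolated levels and are the
independent oracle for every finite-difference path; degenerate levels
raise an error directing to a subspace treatment.

Exciton binding is a deliberate mock: a scalar subtracted from the orbital
gap — zero, constant, or U(r) = U₀·exp(−r/r₀) on one designated bond. It
exists to make the geometry dependence of the two-body term switchable:
"none" and "constant" make the SBA exact (a controlled positive test),
"distance" produces a quantified, localized violation. It is not a
self-consistent interaction; no many-body physics is claimed.

Open-shell systems occupy one extra majority-spin level (spin-restricted
spectrum). SOMO = highest singly occupied level. The SUMO convention is
configurable: the spec-level default "minority_spin" (the SOMO's own
spatial orbital, unoccupied in the minority channel) yields an identically
zero fundamental gap in a spin-restricted one-electron model, so the
radical fixtures and examples use the "same_spin" convention (level above
the SOMO), which carries the physics of interest.

### What the synthetic fixtures emulate — and what they do not

The fixtures emulate molecules with harmonic vibrations whose orbital and
excitation energies respond linearly (optionally quadratically) to
bond-length changes: the SSH/Peierls setting. Default fixture parameters
are chosen at carbon-backbone scale: bond length 1.4 Å, hopping t₀ = 2.5 eV,
electron–phonon coupling α = 4 eV/Å, spring constant 30 eV/Å² (stretch
frequencies around 300–1700 cm⁻¹), mass 12 amu. Chains with only
central-force springs have free transverse motions; these appear as
near-zero frequencies, are reported with a warning and excluded from
sampling — a feature of the minimal spring model, not of the method.
Passing tests therefore demonstrate the correctness of the machinery
(projection, tracking, differencing, sampling, flag logic) and the internal
consistency of the SBA identities; they do not demonstrate that the SBA
holds for any real molecule, which is a statement about real two-body
interactions outside this model's scope.

## Numerical choices

- Units: model energies eV, lengths Å, masses amu; normal coordinates in
  mass-weighted atomic units (Bohr·√mₑ); reports in cm⁻¹ and meV. All
  conversion constants live in `constants.py`.
- Finite-difference step: 1e-3 mass-weighted a.u. by default — small enough
  that truncation is far below reporting precision, large enough to stay
  well clear of rounding noise (verified by the order-2 convergence check
  against the analytic oracle).
- Hessian symmetry tolerance 1e-6 relative (symmetrized on input);
  near-zero frequency threshold 10 cm⁻¹ for classifying residual
  rigid-body/free-motion contamination, configurable.
- Frontier degeneracy tolerance 1 meV at equilibrium triggers the
  SBA-overestimation flag (near-degenerate frontier orbitals are the
  documented failure mode of the approximation); the analysis continues.
- IRAV thresholds: a mode is an IRAV candidate when |ΔE_gap| ≥ 20% of the
  per-system maximum (the notion of "strongly coupled" is descriptive, so
  the knob is explicit), and IR-forbidden when additionally
  |dD/dQ| ≤ 1e-6 a.u. IR intensity is reported as |dD/dQ|², proportional to
  the double-harmonic intensity.
- Rotational projection is on by default but can be disabled for Hessians
  that arrive already rotation-projected.

## Problem sizes

Tests and the acceptance script run on 2–12-site tight-binding systems:
large enough to exhibit level crossings, degenerate frontiers, deep-orbital
responses and localized SBA violations, small enough that everything has a
closed-form or brute-force cross-check. Monte Carlo statistics use 10⁴
samples for variance and normality checks.

## Known limitations

- No analytic orbital derivatives for external quantum-chemistry backends
  (finite differences only); the analytic path is a property of the
  tight-binding oracle.
- No summation of per-mode contributions into a single zero-point
  renormalized gap; the package diagnoses per-mode couplings.
- No Wigner sampling of momenta (only coordinate displacements are needed),
  no anharmonic vibrational analysis, no Raman intensities.
- The two-body binding term is a mock; quantitative exciton physics is out
  of scope.
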