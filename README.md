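# modecouple

Mode-resolved electron–vibration coupling diagnostics from frontier orbital
energy derivatives.

## The problem

Molecular optoelectronic properties — vertical excitation energies, charge
gaps, IR signatures — are modulated by nuclear motion even at 0 K.
Quantifying which vibrations matter normally requires many excited-state
calculations at displaced geometries. This package implements a low-cost
alternative: derivatives of the frontier orbital energies with respect to
normal modes, obtained from ground-state information only, identify the
strongly coupled vibrations.

The core quantities, for a normal mode *Qᵢ* with frequency *ωᵢ*:

- fundamental gap *E*gap = *E*L − *E*H (LUMO minus HOMO energy), and the
  optical gap *E*S1 = *E*gap − *E*bind, where *E*bind is the exciton
  binding energy;
- per-mode changes at the thermal characteristic geometries ±*σᵢ*(T):
  Δ*E*S1(*Qᵢ*) = Δ*E*gap(*Qᵢ*) − Δ*E*bind(*Qᵢ*), with
  *σᵢ*(T)² = coth(ħ*ωᵢ*/2k_BT)/(2*ωᵢ*) in mass-weighted atomic units — the
  width of the quantum thermal coordinate distribution, reducing to the
  zero-point width (2*ωᵢ*)^(−1/2) at T = 0;
- the **static binding approximation (SBA)**: if Δ*E*bind ≪ Δ*E*gap, then
  Δ*E*S1 ≈ Δ*E*gap, and the cheap ground-state quantities d*E*H/d*Qᵢ*,
  d*E*L/d*Qᵢ* rank the electronically active modes;
- **IRAV analysis**: comparing IR intensities |d*D*/d*Qᵢ*|² with per-orbital
  energy derivatives over a window of orbitals around the frontier flags
  infrared-active vibrations — including symmetry-dark modes with no IR
  intensity but strong gap coupling.

A self-contained Hückel–Peierls (SSH-type) tight-binding backend — hoppings
t(r) = t₀ − α(r − r_eq) on harmonic springs, with a controllable mock
exciton-binding term — provides exact analytic (Hellmann–Feynman) orbital
derivatives, making every part of the pipeline verifiable against closed
forms, and doubles as the synthetic-fixture generator. Real
electronic-structure engines plug in through a small backend contract
(`modecouple.coupling.Backend`).

## Worked example

`examples/04_irav_radical_cation.py` runs the IRAV analysis on a
centrosymmetric 4-site radical-cation chain (3 electrons, Peierls coupling
α = 4 eV/Å):

```
mode  freq/cm^-1   |dD/dQ|/au     |dEgap|/meV  flags
   4       631.1     4.065e-12        72.797  IR-FORBIDDEN IRAV
   5      1166.0     2.860e-02        15.374
   6      1523.5     3.698e-12       293.598  IR-FORBIDDEN IRAV
```

The two gerade stretches carry no IR intensity (|d*D*/d*Q*| ≈ 10⁻¹²) yet
modulate the SOMO/SUMO gap by 73 and 294 meV — symmetry-forbidden IRAVs
that only the Δ*E*gap diagnostic reveals. The ungerade mode is IR active
but weakly coupled. See `examples/` for the other capabilities (closed-form
two-site gap modulation, SBA checking with a distance-dependent binding
term, thermal/Monte Carlo sampling).

A thin CLI wraps the same pipeline:

```bash
modecouple demo                 # built-in end-to-end fixture
modecouple modes --tb-model chain.yaml
modecouple couple --tb-model chain.yaml --output-dir out
```

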