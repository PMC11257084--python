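"""Thermal widths and geometry ensembles for a diatomic.

sigma_i(T) is the standard deviation of the quantum thermal coordinate
distribution: (2 omega)^(-1/2) at 0 K, growing with temperature toward the
classical equipartition width.
"""

from modecouple import (
    bose_population,
    linear_chain,
    monte_carlo_geometries,
    normal_mode_analysis,
    thermal_sigma,
)
from modecouple.tb import TightBindingBackend

model = linear_chain(2, t0=2.0, alpha_ep=3.0, spring=25.0, mass=12.0)
backend = TightBindingBackend(model)
system = backend.system()
modes = normal_mode_analysis(system, backend.hessian())
(i,) = modes.real_mode_indices
omega = modes.frequencies_au[i]

print(f"mode frequency: {modes.frequencies_cm[i]:.2f} cm^-1")
print(" T/K     p(T)        sigma(T)/mw-au")
for temp in (0.0, 100.0, 300.0, 1000.0):
    print(f"{temp:5.0f} {bose_population(omega, temp):9.4f} "
          f"{thermal_sigma(omega, temp):14.4f}")

samples = monte_carlo_geometries(system, modes, 300.0, 5, seed=11)
print("\nfirst Monte Carlo bond lengths at 300 K (Angstrom):")
for g in samples:
    print(f"  {abs(g.coordinates[1, 0] - g.coordinates[0, 0]):.5f}   # {g.comment}")
# p(T) = 1 at 0 K (pure zero-point motion); the ensemble bond lengths
# scatter around the 1.4 A equilibrium with width sigma/sqrt(mu).
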