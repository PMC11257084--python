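"""Shared fixtures: small tight-binding models and their normal modes.

Chains with only central-force springs have free transverse motions, so
normal-mode analysis legitimately warns about extra near-zero frequencies;
the ``analyze`` helper silences that expected warning.
"""

import warnings

import numpy as np
import pytest

from modecouple import (
    BindingModel,
    TightBindingBackend,
    TightBindingModel,
    linear_chain,
    normal_mode_analysis,
    ring,
)


def analyze(model):
    """Backend, equilibrium system and normal modes for a TB model."""
    backend = TightBindingBackend(model)
    system = backend.system()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        modes = normal_mode_analysis(system, backend.hessian())
    return backend, system, modes


@pytest.fixture
def chain2():
    """Two-site dimer: the fully closed-form fixture."""
    return linear_chain(2, bond_length=1.4, t0=2.0, alpha_ep=3.0, spring=25.0, mass=12.0)


@pytest.fixture
def chain4():
    """Centrosymmetric 4-site chain at half filling."""
    return linear_chain(4, bond_length=1.4, t0=2.5, alpha_ep=4.0, spring=30.0, mass=12.0)


@pytest.fixture
def chain6_dimerized():
    return linear_chain(6, bond_length=1.4, dimerization=0.05, t0=2.5, alpha_ep=4.0)


@pytest.fixture
def chain8():
    return linear_chain(8, bond_length=1.4, dimerization=0.04, t0=2.5, alpha_ep=4.0)


@pytest.fixture
def ring6():
    """Benzene-like ring: doubly degenerate frontier orbitals."""
    return ring(6, bond_length=1.4, t0=2.5, alpha_ep=4.0)


@pytest.fixture
def radical3():
    """3-site, 3-electron radical: SOMO is the nonbonding level."""
    return linear_chain(3, bond_length=1.4, t0=2.0, alpha_ep=3.0, n_electrons=3)


def random_tb_model(rng, n_max=12):
    """Random chain-topology model for oracle-equivalence checks.

    Distinct random site energies keep the spectrum generically
    non-degenerate; geometry is a mildly bent 3D chain.
    """
    n = int(rng.integers(3, n_max + 1))
    pos = np.zeros((n, 3))
    for i in range(1, n):
        step = np.array([1.0, 0, 0]) + 0.15 * rng.normal(size=3)
        pos[i] = pos[i - 1] + 1.4 * step / np.linalg.norm(step)
    bonds = [(i, i + 1) for i in range(n - 1)]
    return TightBindingModel(
        site_energies=rng.uniform(-0.5, 0.5, n),
        positions=pos,
        masses=rng.uniform(1.0, 20.0, n),
        bonds=bonds,
        t0=rng.uniform(1.0, 3.0, n - 1),
        alpha_ep=rng.uniform(0.5, 5.0, n - 1),
        springs=rng.uniform(10.0, 40.0, n - 1),
    )


def isolated_orbital(result, min_gap=1e-3):
    """Index of the orbital best separated from its neighbours."""
    e = result.energies
    gaps = np.minimum(
        np.diff(e, prepend=e[0] - 10 * min_gap),
        np.diff(e, append=e[-1] + 10 * min_gap),
    )
    return int(np.argmax(gaps))
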