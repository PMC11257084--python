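"""Orbital tracking, gap/optical-gap diagnostics and the SBA report."""

import numpy as np
import pytest

from modecouple import (
    BindingModel,
    NormalModeSet,
    TightBindingBackend,
    delta_gap,
    delta_s1,
    linear_chain,
    mode_coupling_analysis,
    open_shell_gap,
    orbital_energy_derivatives,
    sba_report,
    tb_analytic_orbital_derivative,
    tb_solve,
    thermal_sigma,
    track_orbitals,
    transition_gap_for_state,
)
from modecouple.constants import AMU_ME, BOHR_ANGSTROM, EV_MEV
from modecouple.errors import CapabilityError, ConfigError
from modecouple.tb import TightBindingModel

from conftest import analyze


def two_dimer_model(t_a=2.0, t_b=1.9):
    """Two decoupled dimers whose levels cross when bond A is stretched."""
    pos = np.array([[0, 0, 0], [1.4, 0, 0], [0, 10, 0], [1.4, 10, 0]], float)
    return TightBindingModel(
        site_energies=np.zeros(4),
        positions=pos,
        masses=np.full(4, 12.0),
        bonds=[(0, 1), (2, 3)],
        t0=[t_a, t_b],
        alpha_ep=[3.0, 3.0],
        springs=30.0,
    )


class TestTrackOrbitals:
    def test_identity_for_same_result(self, chain8):
        res = tb_solve(chain8)
        track = track_orbitals(res, res)
        np.testing.assert_array_equal(track.permutation, np.arange(8))
        assert not track.ambiguous.any()

    def test_sign_flips_do_not_matter(self, chain8):
        res = tb_solve(chain8)
        flipped = tb_solve(chain8)
        flipped.vectors = flipped.vectors * np.where(np.arange(8) % 2, -1, 1)
        track = track_orbitals(res, flipped)
        np.testing.assert_array_equal(track.permutation, np.arange(8))

    def test_level_crossing_recovered_as_transposition(self):
        """Stretching dimer A pushes its levels past dimer B's."""
        model = two_dimer_model()
        ref = tb_solve(model)
        pos = model.positions.copy()
        pos[1, 0] += 0.1  # t_A: 2.0 -> 1.7, below t_B = 1.9
        disp = tb_solve(model, pos)
        # brute-force overlap table confirms the crossing is a clean swap
        ov = np.abs(ref.vectors.T @ disp.vectors)
        assert ov[0, 1] > 0.99 and ov[1, 0] > 0.99
        track = track_orbitals(ref, disp)
        np.testing.assert_array_equal(track.permutation, [1, 0, 3, 2])
        assert not track.ambiguous.any()

    def test_dimension_mismatch_rejected(self, chain8, chain4):
        with pytest.raises(ConfigError):
            track_orbitals(tb_solve(chain8), tb_solve(chain4))


class TestOrbitalDerivatives:
    def test_two_site_closed_form(self, chain2):
        backend, system, modes = analyze(chain2)
        (i,) = modes.real_mode_indices
        table = orbital_energy_derivatives(backend, system, modes, mode_indices=[i])
        alpha = chain2.alpha_ep[0]
        # hand conversion: dr/dq for the stretch of two equal masses
        dr_dq = np.sqrt(2.0 / (chain2.masses[0] * AMU_ME)) * BOHR_ANGSTROM
        d_h = float(table[table.orbital == 0].derivative_mev_per_q.iloc[0])
        d_l = float(table[table.orbital == 1].derivative_mev_per_q.iloc[0])
        expected = alpha * dr_dq * EV_MEV
        assert abs(d_h) == pytest.approx(expected, rel=1e-6)
        assert d_l == pytest.approx(-d_h, rel=1e-9)

    def test_translation_mode_gives_zero(self, chain8):
        """A translation-contaminated 'mode' produces no energy response."""
        backend, system, modes = analyze(chain8)
        t = np.zeros((8, 3))
        t[:, 0] = np.sqrt(system.masses * AMU_ME)
        vec = (t / np.linalg.norm(t)).ravel()[:, None]
        fake = NormalModeSet(
            frequencies_cm=np.array([500.0]),
            frequencies_au=np.array([500.0 / 219474.63]),
            vectors=vec,
            reduced_masses=np.array([1.0]),
            masses=system.masses,
            n_projected=0,
            linear=True,
        )
        table = orbital_energy_derivatives(backend, system, fake, mode_indices=[0])
        assert np.all(np.abs(table.derivative_mev_per_q) < 1e-10 * EV_MEV)

    def test_matches_hellmann_feynman_oracle_all_modes(self, chain8):
        backend, system, modes = analyze(chain8)
        table = orbital_energy_derivatives(
            backend, system, modes, orbital_window=(2, 2), step=1e-3
        )
        for _, row in table.iterrows():
            direction = modes.cartesian_displacement(int(row["mode"]), 1.0)
            ana = tb_analytic_orbital_derivative(
                chain8, None, int(row["orbital"]), direction
            ) * EV_MEV
            assert row["derivative_mev_per_q"] == pytest.approx(ana, rel=1e-7, abs=5e-8)

    def test_second_order_convergence_in_step(self):
        """Central differences converge with slope 2 against the analytic oracle.

        A light-atom, strong-coupling chain keeps the truncation error well
        above the floating-point noise floor over the whole step range.
        """
        model = linear_chain(6, bond_length=1.0, dimerization=0.008, t0=1.5,
                             alpha_ep=24.0, spring=20.0, mass=1.008)
        backend, system, modes = analyze(model)
        i = int(modes.real_mode_indices[-1])
        ref = tb_solve(model)
        k = ref.homo_index
        direction = modes.cartesian_displacement(i, 1.0)
        ana = tb_analytic_orbital_derivative(model, None, k, direction) * EV_MEV
        steps = np.geomspace(1e-2, 1e-4, 7)
        errs = []
        for h in steps:
            table = orbital_energy_derivatives(
                backend, system, modes, step=h, mode_indices=[i]
            )
            d = float(table[table.orbital == k].derivative_mev_per_q.iloc[0])
            errs.append(abs(d - ana))
        slope = np.polyfit(np.log(steps), np.log(errs), 1)[0]
        assert slope == pytest.approx(2.0, abs=0.1)

    def test_missing_capability_rejected(self, chain8):
        backend, system, modes = analyze(chain8)

        class NoGround:
            capabilities = frozenset()
            def evaluate(self, s):  # pragma: no cover
                raise AssertionError

        with pytest.raises(CapabilityError):
            orbital_energy_derivatives(NoGround(), system, modes)


class TestDeltaGap:
    def test_two_site_closed_form(self, chain2):
        backend, system, modes = analyze(chain2)
        (i,) = modes.real_mode_indices
        records = delta_gap(backend, system, modes, temperature=0.0, mode_indices=[i],
                            include_derivatives=False, include_dipole=False)
        (rec,) = records
        sigma = thermal_sigma(modes.frequencies_au[i], 0.0)
        dr = sigma * np.sqrt(2.0 / (chain2.masses[0] * AMU_ME)) * BOHR_ANGSTROM
        expected = 2 * chain2.alpha_ep[0] * dr * EV_MEV  # gap(r) = 2 t(r), exactly linear
        assert rec.dgap == pytest.approx(expected, rel=1e-10)
        assert rec.dgap_plus == pytest.approx(-rec.dgap_minus, rel=1e-10)

    def test_zero_coupling_mode_gives_zero(self):
        model = linear_chain(4, alpha_ep=0.0)
        backend, system, modes = analyze(model)
        records = delta_gap(backend, system, modes, include_derivatives=False,
                            include_dipole=False)
        for rec in records:
            assert rec.dgap == pytest.approx(0.0, abs=1e-10)

    def test_asymmetry_vanishes_for_linear_coupling(self, chain2):
        # two-site gap is exactly 2 t(r), linear in the stretch coordinate
        backend, system, modes = analyze(chain2)
        records = delta_gap(backend, system, modes, include_derivatives=False,
                            include_dipole=False)
        for rec in records:
            assert abs(rec.dgap_asymmetry) < 1e-10

    def test_quadratic_coupling_creates_asymmetry_matching_parabola(self):
        """Independent parabola fit of E_gap(q) predicts the +/- asymmetry."""
        model = linear_chain(2, t0=2.0, alpha_ep=3.0, alpha_ep2=8.0, spring=25.0)
        backend, system, modes = analyze(model)
        (i,) = modes.real_mode_indices
        sigma = thermal_sigma(modes.frequencies_au[i], 0.0)
        qs = np.linspace(-1.5 * sigma, 1.5 * sigma, 11)
        gaps = []
        for q in qs:
            pos = system.coordinates + modes.cartesian_displacement(i, q)
            gaps.append(tb_solve(model, pos).gap())
        a2, a1, a0 = np.polyfit(qs, gaps, 2)
        records = delta_gap(backend, system, modes, mode_indices=[i],
                            include_derivatives=False, include_dipole=False)
        (rec,) = records
        assert rec.dgap_asymmetry == pytest.approx(a2 * sigma**2 * EV_MEV, rel=1e-6)
        # symmetric/antisymmetric parts recombine to the raw signed values
        assert rec.dgap_asymmetry + rec.dgap_symmetric == pytest.approx(rec.dgap_plus)
        assert rec.dgap_asymmetry - rec.dgap_symmetric == pytest.approx(rec.dgap_minus)

    def test_degenerate_frontier_flagged_without_crash(self, ring6):
        backend, system, modes = analyze(ring6)
        records = delta_gap(backend, system, modes, include_derivatives=False,
                            include_dipole=False)
        assert records
        for rec in records:
            assert "degenerate_frontier_sba_overestimate" in rec.flags


class TestDeltaS1:
    @pytest.mark.parametrize("binding", [
        BindingModel(kind="none"),
        BindingModel(kind="constant", u0=0.5),
    ])
    def test_sba_exact_when_binding_static(self, chain8, binding):
        backend, system, modes = analyze(chain8.with_binding(binding))
        records = delta_s1(backend, system, modes, include_derivatives=False,
                           include_dipole=False)
        for rec in records:
            assert rec.ds1_plus == pytest.approx(rec.dgap_plus, abs=1e-12)
            assert rec.ds1_minus == pytest.approx(rec.dgap_minus, abs=1e-12)
            assert rec.dbind_plus == pytest.approx(0.0, abs=1e-12)

    def test_distance_binding_gap_s1_difference_is_delta_u(self, chain8):
        binding = BindingModel(kind="distance", u0=0.4, r0=2.0, bond=(3, 4))
        model = chain8.with_binding(binding)
        backend, system, modes = analyze(model)
        records = delta_s1(backend, system, modes, include_derivatives=False,
                           include_dipole=False)
        u0 = binding.evaluate(system.coordinates)
        for rec in records:
            sigma = rec.sigma
            for sign, dbind in ((+1, rec.dbind_plus), (-1, rec.dbind_minus)):
                pos = system.coordinates + modes.cartesian_displacement(
                    rec.mode_index, sign * sigma
                )
                du = binding.evaluate(pos) - u0
                # Delta E_bind = Delta E_gap - Delta E_S1 = +Delta U
                assert dbind == pytest.approx(du * EV_MEV, abs=1e-10)

    def test_requires_excited_states(self, chain8):
        backend, system, modes = analyze(chain8)

        class GroundOnly:
            capabilities = frozenset({"ground_state"})
            def evaluate(self, s):
                return backend.evaluate(s)

        with pytest.raises(CapabilityError):
            delta_s1(GroundOnly(), system, modes)


class TestSbaReport:
    def test_perfect_diagonal_r2_is_one(self, chain8):
        backend, system, modes = analyze(chain8)
        records = delta_s1(backend, system, modes, include_derivatives=False,
                           include_dipole=False)
        report = sba_report(records)
        assert report.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_zero_gap_variance_flags_degenerate(self, chain8):
        backend, system, modes = analyze(chain8)
        records = delta_s1(backend, system, modes, include_derivatives=False,
                           include_dipole=False)
        for rec in records:  # fabricate: no gap response, real S1 response
            rec.dgap_plus = rec.dgap_minus = 0.0
        report = sba_report(records)
        assert report.r_squared == 0.0
        assert "degenerate_variance" in report.flags

    def test_distance_binding_outlier_is_designated_bond_stretch(self, chain8):
        """The mode stretching the U(r) bond is the largest SBA violator."""
        binding = BindingModel(kind="distance", u0=0.4, r0=2.0, bond=(3, 4))
        model = chain8.with_binding(binding)
        backend, system, modes = analyze(model)
        records = delta_s1(backend, system, modes, include_derivatives=False,
                           include_dipole=False)
        viol = {r.mode_index: abs(r.dbind_plus) + abs(r.dbind_minus) for r in records}
        worst = max(viol, key=viol.get)
        # independent construction: which mode most changes the 3-4 bond length
        stretch = {}
        for r in records:
            d = modes.cartesian_displacement(r.mode_index, r.sigma)
            stretch[r.mode_index] = abs(
                np.linalg.norm((system.coordinates + d)[4] - (system.coordinates + d)[3])
                - np.linalg.norm(system.coordinates[4] - system.coordinates[3])
            )
        assert worst == max(stretch, key=stretch.get)
        report = sba_report(records)
        assert report.r_squared < 1.0

    def test_ranking_and_strong_fraction(self, chain8):
        backend, system, modes = analyze(chain8)
        records = delta_gap(backend, system, modes, include_derivatives=False,
                            include_dipole=False)
        report = sba_report(records, strong_fraction=0.2)
        gaps = {r.mode_index: abs(r.dgap) for r in records}
        assert report.ranked_modes == sorted(gaps, key=gaps.get, reverse=True)
        mx = max(gaps.values())
        assert set(report.strong_modes) == {m for m, g in gaps.items() if g >= 0.2 * mx}
        assert report.r_squared is None  # no S1 data present


class TestTransitionGapForState:
    def test_homo_lumo_state_matches_delta_gap(self, chain8):
        backend, system, modes = analyze(chain8)
        recs_a = transition_gap_for_state(backend, system, modes,
                                          include_derivatives=False, include_dipole=False)
        recs_b = delta_gap(backend, system, modes,
                           include_derivatives=False, include_dipole=False)
        for a, b in zip(recs_a, recs_b):
            assert a.dgap_plus == pytest.approx(b.dgap_plus, abs=1e-12)
            assert a.frontier == b.frontier

    def test_homo_minus_one_state_follows_designated_pair(self, chain4):
        """S1 built as HOMO-1 -> LUMO: reported gap is eps_L - eps_{H-1}."""
        from dataclasses import replace

        model = replace(chain4, s1_pair=(1, 0))
        model.__post_init__()
        backend, system, modes = analyze(model)
        recs = transition_gap_for_state(backend, system, modes,
                                        include_derivatives=False, include_dipole=False)
        ref = tb_solve(model)
        pair = (ref.homo_index - 1, ref.lumo_index)
        for rec in recs:
            assert rec.frontier == pair
            # oracle: direct evaluation of the tracked pair gap at +/- sigma
            e0 = ref.energies[pair[1]] - ref.energies[pair[0]]
            for sign, got in ((+1, rec.dgap_plus), (-1, rec.dgap_minus)):
                pos = system.coordinates + modes.cartesian_displacement(
                    rec.mode_index, sign * rec.sigma
                )
                res = tb_solve(model, pos)
                track = track_orbitals(ref, res)
                e = (res.energies[track.follow(pair[1])]
                     - res.energies[track.follow(pair[0])])
                assert got == pytest.approx((e - e0) * EV_MEV, abs=1e-10)

    def test_degenerate_donor_flagged_with_candidates(self, ring6):
        backend, system, modes = analyze(ring6)
        recs = transition_gap_for_state(backend, system, modes,
                                        include_derivatives=False, include_dipole=False)
        assert recs
        flags = set().union(*(r.flags for r in recs))
        assert "degenerate_donor_acceptor" in flags
        assert any(f.startswith("candidate_pairs:") for f in recs[0].flags)


class TestOpenShell:
    def test_closed_shell_input_directed_to_delta_gap(self, chain8):
        backend, system, modes = analyze(chain8)
        with pytest.raises(ConfigError, match="delta_gap"):
            open_shell_gap(backend, system, modes)

    def test_radical_somo_is_nonbonding_level(self, radical3):
        res = tb_solve(radical3)
        assert res.open_shell
        assert res.energies[res.somo_index] == pytest.approx(0.0, abs=1e-12)
        assert res.sumo_index("minority_spin") == res.somo_index
        assert res.sumo_index("same_spin") == res.somo_index + 1

    def test_radical_gap_follows_three_site_closed_form(self, radical3):
        """Spectrum {0, +/-sqrt(t1^2 + t2^2)} gives the gap in closed form."""
        backend, system, modes = analyze(radical3)
        recs = open_shell_gap(backend, system, modes, sumo_convention="same_spin",
                              include_derivatives=False, include_dipole=False)
        gap0 = np.sqrt(2.0) * radical3.t0[0]
        for rec in recs:
            for sign, got in ((+1, rec.dgap_plus), (-1, rec.dgap_minus)):
                pos = system.coordinates + modes.cartesian_displacement(
                    rec.mode_index, sign * rec.sigma
                )
                r1 = np.linalg.norm(pos[1] - pos[0])
                r2 = np.linalg.norm(pos[2] - pos[1])
                t1 = radical3.t0[0] - radical3.alpha_ep[0] * (r1 - radical3.equilibrium_bond_lengths[0])
                t2 = radical3.t0[1] - radical3.alpha_ep[1] * (r2 - radical3.equilibrium_bond_lengths[1])
                expected = (np.hypot(t1, t2) - gap0) * EV_MEV
                assert got == pytest.approx(expected, abs=1e-8)

    def test_cation_with_stronger_coupling_responds_more(self):
        neutral = linear_chain(4, alpha_ep=2.0)
        cation = linear_chain(4, alpha_ep=6.0, n_electrons=3)
        bn, sn, mn = analyze(neutral)
        bc, sc, mcm = analyze(cation)
        rec_n = delta_gap(bn, sn, mn, include_derivatives=False, include_dipole=False)
        rec_c = open_shell_gap(bc, sc, mcm, sumo_convention="same_spin",
                               include_derivatives=False, include_dipole=False)
        assert max(abs(r.dgap) for r in rec_c) > max(abs(r.dgap) for r in rec_n)

    def test_spin_channels_consistent(self, radical3):
        res = tb_solve(radical3)
        # one shared spatial spectrum: alpha occupies one more level than beta
        assert res.occupations_alpha.sum() == 2
        assert res.occupations_beta.sum() == 1
        np.testing.assert_array_equal(
            res.occupations, res.occupations_alpha + res.occupations_beta
        )
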