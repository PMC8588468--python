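import numpy as np
import pytest

import ioneda as io
from ioneda.basis import BasisSpec
from ioneda.geometry import atom, center_of_nuclear_charge
from ioneda.integrals import ao_integrals
from ioneda.periodic import AU_TO_DEBYE, COULOMB_KCAL_ANGSTROM, HARTREE_TO_KCAL
from ioneda.sapt import (EDAResult, UnconvergedInputError, assemble_eda,
                         compute_dipole, cross_nuclear_repulsion, delta_hf,
                         elst1, embedding_potential, exch1,
                         heitler_london_energy, induction_resp,
                         supramolecular_hf)
from ioneda.scf import solve_scf
from ioneda.synth import generate_binary_complex

MIN = BasisSpec("min")
K = HARTREE_TO_KCAL
DEBYE_TO_EA = 0.2081943


def dipole_aligned_water(r):
    """Water at distance r on +z with its C2 axis pointing at the origin."""
    import math
    half = math.radians(104.52 / 2)
    ro = 0.9572
    return [atom("O", [0, 0, r]),
            atom("H", [ro * math.sin(half), 0, r - ro * math.cos(half)]),
            atom("H", [-ro * math.sin(half), 0, r - ro * math.cos(half)])]


def _dimer_solutions(atoms, ia, ib, qa, qb, basis=MIN):
    ints = ao_integrals(atoms, basis)
    sol_d = solve_scf(integrals=ints, charge=qa + qb)
    sol_a = solve_scf(integrals=ints.with_ghosts(ib), charge=qa)
    sol_b = solve_scf(integrals=ints.with_ghosts(ia), charge=qb)
    return ints, sol_d, sol_a, sol_b


class TestElectrostatics:
    def test_point_charge_limit_at_100_angstrom(self):
        atoms = [atom("Cl", [0, 0, 0]), atom("Cl", [0, 0, 100.0])]
        ints, _, sa, sb = _dimer_solutions(atoms, [0], [1], -1, -1)
        e = elst1(sa, sb, ints, [0], [1]) * K
        assert e == pytest.approx(COULOMB_KCAL_ANGSTROM / 100.0, rel=1e-3)

    def test_charge_dipole_limit_at_50_angstrom(self):
        # water with its C2 (dipole) axis aligned on the ion direction, so
        # the charge-dipole term dominates the multipole expansion
        atoms = [atom("Cl", [0, 0, 0])] + dipole_aligned_water(50.0)
        ia, ib = [0], [1, 2, 3]
        ints, _, sa, sb = _dimer_solutions(atoms, ia, ib, -1, 0)
        e = elst1(sa, sb, ints, ia, ib) * K

        water = [atoms[i] for i in ib]
        w_ints = ao_integrals(water, MIN)
        w_sol = solve_scf(integrals=w_ints, charge=0)
        _, mu_vec = compute_dipole(water, w_sol.density, w_ints)
        origin = center_of_nuclear_charge(water)
        rvec = atoms[ia[0]].position - origin
        r = np.linalg.norm(rvec)
        pred = (COULOMB_KCAL_ANGSTROM * (-1.0)
                * (mu_vec * DEBYE_TO_EA) @ (rvec / r) / r ** 2)
        assert e == pytest.approx(pred, rel=0.01)
        assert e < 0

    def test_swap_symmetry(self, clw_monomers):
        ints, _, sa, sb, ia, ib = clw_monomers
        assert elst1(sa, sb, ints, ia, ib) == \
            pytest.approx(elst1(sb, sa, ints, ib, ia), abs=1e-12)

    def test_unconverged_input_rejected(self, clw_monomers):
        ints, _, sa, sb, ia, ib = clw_monomers
        import copy
        bad = copy.copy(sb)
        bad.converged = False
        with pytest.raises(UnconvergedInputError):
            elst1(sa, bad, ints, ia, ib)


class TestExchange:
    def test_vanishes_at_long_range(self):
        snap = generate_binary_complex("Cl-", 16.0)
        ia = list(snap.ion.indices)
        ib = list(snap.water_cluster_fragment().indices)
        ints, _, sa, sb = _dimer_solutions(snap.atoms, ia, ib, -1, 0)
        assert abs(exch1(sa, sb, ints, ia, ib) * K) < 1e-8

    def test_positive_at_hbond_contact_and_swap_symmetric(self, clw_monomers):
        ints, _, sa, sb, ia, ib = clw_monomers
        e = exch1(sa, sb, ints, ia, ib)
        assert e > 0
        assert e == pytest.approx(exch1(sb, sa, ints, ib, ia), abs=1e-12)

    def test_matches_independent_determinant_oracle(self, clw_monomers):
        """Antisymmetrized-product expectation value recomputed with an
        independent AO-contraction route (explicit transition density and
        raw integral tensors)."""
        ints, _, sa, sb, ia, ib = clw_monomers
        e_impl = exch1(sa, sb, ints, ia, ib)

        C = np.hstack([sa.occ_coeff, sb.occ_coeff])
        S = ints.overlap
        G = np.linalg.inv(C.T @ S @ C)
        M = C @ G @ C.T
        h = ints.kinetic + ints.nuclear(ia + ib)
        eri = ints.eri
        e_hl = (2.0 * np.sum(M * h)
                + 2.0 * np.einsum("ijkl,ji,lk->", eri, M, M, optimize=True)
                - np.einsum("ijkl,jk,li->", eri, M, M, optimize=True)
                + ints.nuclear_repulsion(ia + ib))
        da, db = sa.density, sb.density
        e_a = (np.sum(da * (ints.kinetic + ints.nuclear(ia)))
               + 0.5 * np.einsum("ijkl,ji,lk->", eri, da, da, optimize=True)
               - 0.25 * np.einsum("ijkl,jk,li->", eri, da, da, optimize=True)
               + ints.nuclear_repulsion(ia))
        e_b = (np.sum(db * (ints.kinetic + ints.nuclear(ib)))
               + 0.5 * np.einsum("ijkl,ji,lk->", eri, db, db, optimize=True)
               - 0.25 * np.einsum("ijkl,jk,li->", eri, db, db, optimize=True)
               + ints.nuclear_repulsion(ib))
        e_elst = (cross_nuclear_repulsion(ints.atoms, ia, ib)
                  + np.sum(da * ints.nuclear(ib)) + np.sum(db * ints.nuclear(ia))
                  + np.einsum("ijkl,ji,lk->", eri, da, db, optimize=True))
        e_oracle = e_hl - e_a - e_b - e_elst
        assert e_impl == pytest.approx(e_oracle, abs=1e-9)


class TestInduction:
    def test_zero_field_gives_zero(self, clw_monomers):
        ints, _, sa, sb, ia, ib = clw_monomers
        from ioneda.sapt import cphf_response
        e, x = cphf_response(sa, ints, np.zeros((ints.nbf, ints.nbf)))
        assert abs(e) < 1e-10
        assert np.all(x == 0)

    def test_each_direction_nonpositive(self, clw_monomers):
        ints, _, sa, sb, ia, ib = clw_monomers
        e_ab, _, _ = induction_resp(sa, sb, ints, ia, ib)
        e_ba, _, _ = induction_resp(sb, sa, ints, ib, ia)
        assert e_ab <= 0 and e_ba <= 0

    def test_matches_finite_field_frozen_potential_oracle(self, clw_monomers):
        """Coupled response vs the quadratic part of embedded SCF runs in
        the scaled frozen potential of the partner (Richardson
        extrapolation of the symmetric second difference)."""
        ints, _, sa, sb, ia, ib = clw_monomers
        e_cphf, _, _ = induction_resp(sa, sb, ints, ia, ib)
        v = embedding_potential(sb, ints, ib)
        ints_a = ints.with_ghosts(ib)

        def energy(lam):
            if lam == 0.0:
                return sa.energy
            sol = solve_scf(integrals=ints_a, charge=-1,
                            extra_potential=lam * v,
                            init_density=sa.density, conv_tol=1e-13)
            return sol.energy - lam * np.einsum("ij,ij->", sa.density, v)

        e0 = energy(0.0)

        def second(lam):
            return (energy(lam) + energy(-lam) - 2 * e0) / lam ** 2

        s1, s2, s3 = second(0.1), second(0.05), second(0.025)
        r1 = (4 * s2 - s1) / 3
        r2 = (4 * s3 - s2) / 3
        e_ff = (16 * r2 - r1) / 15
        assert e_cphf == pytest.approx(e_ff, abs=1e-6)

    def test_exchange_induction_decays_at_long_range(self):
        snap = generate_binary_complex("Cl-", 16.0)
        ia = list(snap.ion.indices)
        ib = list(snap.water_cluster_fragment().indices)
        ints, _, sa, sb = _dimer_solutions(snap.atoms, ia, ib, -1, 0)
        _, xind, _ = induction_resp(sa, sb, ints, ia, ib)
        assert abs(xind * K) < 1e-8


class TestSupramolecularAndDeltaHF:
    def test_far_separation_interaction_vanishes(self):
        snap = generate_binary_complex("Cl-", 500.0)
        ia = list(snap.ion.indices)
        ib = list(snap.water_cluster_fragment().indices)
        ints, sd, sa, sb = _dimer_solutions(snap.atoms, ia, ib, -1, 0)
        assert abs(supramolecular_hf(sd, sa, sb)) < 1e-6

    def test_definition_identity(self, clw_monomers):
        ints, sd, sa, sb, ia, ib = clw_monomers
        assert supramolecular_hf(sd, sa, sb) == \
            pytest.approx(sd.energy - sa.energy - sb.energy, abs=1e-14)

    def test_rotation_invariance(self, clw_snapshot):
        from test_integrals_scf import _rotate
        snap = clw_snapshot
        ia = list(snap.ion.indices)
        ib = list(snap.water_cluster_fragment().indices)
        _, sd, sa, sb = _dimer_solutions(snap.atoms, ia, ib, -1, 0)
        e0 = supramolecular_hf(sd, sa, sb)
        rot = _rotate(snap.atoms, [1, 1, 0], 1.1)
        _, sd2, sa2, sb2 = _dimer_solutions(rot, ia, ib, -1, 0)
        assert supramolecular_hf(sd2, sa2, sb2) == pytest.approx(e0, abs=1e-8)

    def test_delta_hf_zero_for_contrived_inputs(self):
        assert delta_hf(-10.0, -8.0, 4.0, -3.0, -2.0, 0.5, -1.5) == \
            pytest.approx(0.0, abs=1e-12)

    def test_closure_after_adding_delta(self, clw_monomers):
        ints, sd, sa, sb, ia, ib = clw_monomers
        e_el = elst1(sa, sb, ints, ia, ib)
        e_x = exch1(sa, sb, ints, ia, ib)
        i_ab, x_ab, _ = induction_resp(sa, sb, ints, ia, ib)
        i_ba, x_ba, _ = induction_resp(sb, sa, ints, ib, ia)
        e_hf = supramolecular_hf(sd, sa, sb)
        d = delta_hf(e_hf, e_el, e_x, i_ab, i_ba, x_ab, x_ba)
        total_ind = i_ab + i_ba + x_ab + x_ba + d
        assert e_el + e_x + total_ind == pytest.approx(e_hf, abs=1e-12)


class TestAssemble:
    COMP = {"elst": -0.03, "exch": 0.025, "ind_ab": -0.01, "ind_ba": -0.002,
            "exchind_ab": 0.004, "exchind_ba": 0.001, "e_int_hf": -0.015}

    def test_sum_identities_and_grouping(self):
        res = assemble_eda(self.COMP, dispersion=-1.5)
        assert res.e_int == pytest.approx(
            res.e_elst + res.e_exch + res.e_ind + res.e_disp, abs=1e-6)
        assert res.e_elst + res.e_exch + res.e_ind == \
            pytest.approx(res.e_int_hf, abs=1e-6)
        assert res.e_elst_exch == pytest.approx(res.e_elst + res.e_exch)

    def test_unit_conversion(self):
        comp = dict(self.COMP, elst=0.1, exch=0.0, ind_ab=0.0, ind_ba=0.0,
                    exchind_ab=0.0, exchind_ba=0.0, e_int_hf=0.1)
        res = assemble_eda(comp, dispersion=0.0)
        assert res.e_elst == pytest.approx(62.75095, abs=1e-6)

    def test_missing_component_raises(self):
        bad = {k: v for k, v in self.COMP.items() if k != "exch"}
        with pytest.raises(KeyError, match="exch"):
            assemble_eda(bad, dispersion=0.0)

    def test_ct_split_identity(self):
        res = assemble_eda(self.COMP, dispersion=-1.0,
                           ct_split=(-0.8, None))
        e_pol = res.e_ind - (-0.8)
        res = assemble_eda(self.COMP, dispersion=-1.0,
                           ct_split=(-0.8, e_pol))
        assert res.e_pol + res.e_ct == pytest.approx(res.e_ind, abs=1e-10)


class TestDipole:
    def test_spherical_anion_is_zero(self):
        cl = [atom("Cl", [3.0, -2.0, 1.0])]
        ints = ao_integrals(cl, MIN)
        sol = solve_scf(integrals=ints, charge=-1)
        mag, _ = compute_dipole(cl, sol.density, ints)
        assert mag < 1e-6

    def test_tetrahedral_perchlorate_is_zero(self):
        d = 1.45 / np.sqrt(3.0)
        atoms = [atom("Cl", [0, 0, 0])] + [
            atom("O", [sx * d, sy * d, sz * d])
            for sx, sy, sz in [(1, 1, 1), (1, -1, -1), (-1, 1, -1),
                               (-1, -1, 1)]]
        ints = ao_integrals(atoms, MIN)
        sol = solve_scf(integrals=ints, charge=-1)
        mag, _ = compute_dipole(atoms, sol.density, ints)
        assert mag < 0.005

    def test_translation_invariance_for_charged_species(self):
        base = [atom("O", [0, 0, 0]), atom("H", [0.9572, 0, 0])]
        # hydroxide-like closed-shell anion
        ints0 = ao_integrals(base, MIN)
        sol0 = solve_scf(integrals=ints0, charge=-1)
        mag0, _ = compute_dipole(base, sol0.density, ints0)
        moved = [atom(a.symbol, a.position + np.array([5.0, -3.0, 2.0]))
                 for a in base]
        ints1 = ao_integrals(moved, MIN)
        sol1 = solve_scf(integrals=ints1, charge=-1)
        mag1, _ = compute_dipole(moved, sol1.density, ints1)
        assert mag1 == pytest.approx(mag0, abs=1e-8)
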