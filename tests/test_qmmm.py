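"""Mutual polarization: surrogate backend, joint variational minimum, forces."""

import numpy as np
import pytest

import polqmmm as pq
from polqmmm import ffio, fixtures, mm_energy, polarization, qmmm, units
from polqmmm.errors import ConvergenceError, PolQmmmError, ValidationError
from conftest import coords_bohr, fd_force_check


def _joint_dense_epol(system, coords):
    """Oracle: solve the full joint polarization problem in one dense solve."""
    el = system.electro
    gm = mm_energy.rotate_multipoles_to_global(el, coords)
    pol, src, tgt, w = system._field_pairs(coords)
    E, _ = system._static_field(gm, coords, pol, src, tgt, w)
    op = polarization.build_thole_interaction(coords, el.alpha, el.thole,
                                              site_index=pol)
    mu = np.linalg.solve(op.matrix, E.reshape(-1))
    return float(-0.5 * mu @ E.reshape(-1)), mu.reshape(-1, 3), pol


class TestSurrogateBackend:
    def test_rigid_charges_converge_in_one_cycle(self, chain3):
        st, pr, spec = chain3
        q, _ = fixtures.surrogate_site_model(st, pr, spec.qm_atom_ids,
                                             polarizable=False)
        backend = pq.SurrogateBackend(q)  # alpha = 0 on the QM side
        system = pq.QmmmSystem(st, pr, spec, backend)
        state, _ = system.energy_and_forces(coords_bohr(st), want_forces=False)
        assert state.cycles == 1
        assert state.converged

    def test_all_rigid_no_polarization(self):
        """With every polarizability zeroed the SCF is a single macro-cycle
        and E_pol vanishes."""
        st, pr = fixtures.make_water_droplet(3, seed=2)
        pr.polarize = {t: (0.0, 0.39, g[2]) for t, g in pr.polarize.items()}
        system = pq.QmmmSystem(st, pr)
        state, _ = system.energy_and_forces(coords_bohr(st), want_forces=False)
        assert state.cycles == 1
        assert state.e_pol_env == 0.0

    def test_charge_count_mismatch_rejected(self, chain3):
        st, pr, spec = chain3
        backend = pq.SurrogateBackend(np.array([0.1, -0.1]))
        with pytest.raises(ValidationError, match="charges"):
            pq.QmmmSystem(st, pr, spec, backend)

    def test_backend_registry(self):
        b = qmmm.get_backend("surrogate", charges=np.array([0.1]))
        assert isinstance(b, pq.SurrogateBackend)
        with pytest.raises(PolQmmmError, match="not registered"):
            qmmm.get_backend("dft-of-doom")

    def test_symmetric_pair_side_exchange(self):
        """Two identical polarizable charge sites: which side of the QM/MM
        divide hosts which is immaterial for the joint energy."""
        coords = np.array([[0.0, 0.0, 0.0], [4.0, 0.0, 0.0]])
        energies = []
        for qm_first in (True, False):
            st = ffio.Structure(["X", "Y"], np.array([91, 92]), coords *
                                units.ANGSTROM_PER_BOHR, set())
            pr = ffio.ForceFieldParams()
            for t in (91, 92):
                pr.atoms[t] = ("X", 10.0)
                pr.vdw[t] = (3.0, 0.0, 1.0)
                pr.multipoles[t] = ffio.MultipoleRecord(
                    0.3, np.zeros(3), np.zeros((3, 3)), "none", ())
                pr.polarize[t] = (0.5, 0.39, ())
            qm_atom = 0 if qm_first else 1
            spec = ffio.PartitionSpec({qm_atom}, set(), "pseudobond")
            backend = pq.SurrogateBackend(np.array([0.3]),
                                          np.array([0.5 * units.BOHR_PER_ANGSTROM ** 3]))
            system = pq.QmmmSystem(st, pr, spec, backend)
            state, _ = system.energy_and_forces(coords, want_forces=False)
            energies.append(state.e_total)
        assert energies[0] == pytest.approx(energies[1], abs=1e-12)


class TestMutualPolarization:
    def test_matches_joint_dense_solve(self, solvated_system):
        x = coords_bohr(solvated_system.structure)
        state, _ = solvated_system.energy_and_forces(x, want_forces=False)
        e_oracle, mu_oracle, pol = _joint_dense_epol(solvated_system, x)
        assert state.cycles > 1
        assert abs(state.e_pol_env - e_oracle) < 1e-10
        assert np.abs(state.mu[pol] - mu_oracle).max() < 1e-8

    def test_functional_decreases_monotonically(self, solvated_system):
        x = coords_bohr(solvated_system.structure)
        state, _ = solvated_system.energy_and_forces(x, want_forces=False)
        trace = np.array(state.trace)
        assert np.all(np.diff(trace) <= 1e-14)

    def test_minimal_joint_fixture_6x6_oracle(self):
        """One surrogate site + one MM polarizable site: the joint dipoles
        match the 6x6 dense solve."""
        coords = np.array([[0.0, 0.0, 0.0], [5.0, 0.0, 0.0],
                           [0.0, 6.0, 0.0]])
        st = ffio.Structure(["X", "Y", "Z"], np.array([91, 92, 93]),
                            coords * units.ANGSTROM_PER_BOHR, set())
        pr = ffio.ForceFieldParams()
        for t, q in ((91, 0.2), (92, -0.3), (93, 0.1)):
            pr.atoms[t] = ("X", 10.0)
            pr.vdw[t] = (3.0, 0.0, 1.0)
            pr.multipoles[t] = ffio.MultipoleRecord(
                q, np.zeros(3), np.zeros((3, 3)), "none", ())
        pr.polarize[92] = (0.4, 0.39, ())
        spec = ffio.PartitionSpec({0}, set(), "pseudobond")
        backend = pq.SurrogateBackend(np.array([0.2]), np.array([2.0]))
        system = pq.QmmmSystem(st, pr, spec, backend)
        state, _ = system.energy_and_forces(coords, want_forces=False)
        e_oracle, mu_oracle, pol = _joint_dense_epol(system, coords)
        assert state.e_pol_env == pytest.approx(e_oracle, abs=1e-12)
        np.testing.assert_allclose(state.mu[pol], mu_oracle, atol=1e-10)

    def test_scf_convergence_error_carries_trace(self, solvated_system):
        with pytest.raises(ConvergenceError) as exc:
            qmmm.scf_mutual_polarization(
                solvated_system, coords_bohr(solvated_system.structure),
                tol=1e-15, max_cycles=2)
        assert len(exc.value.history) == 2


class TestEnvironmentDescriptor:
    def test_pb_atoms_never_classical_sources(self, chain3_system):
        x = coords_bohr(chain3_system.structure)
        gm = mm_energy.rotate_multipoles_to_global(chain3_system.electro, x)
        desc = qmmm.assemble_environment_operators(
            gm, x, None, chain3_system.boundary)
        assert not (set(desc.site_ids) & chain3_system.boundary.qm_atoms)
        # feeding unadjusted multipoles (PB atom still charged) must fail
        gm_raw = mm_energy.rotate_multipoles_to_global(
            chain3_system.atomic, x)
        with pytest.raises(ValidationError, match="PB atom"):
            qmmm.assemble_environment_operators(gm_raw, x, None,
                                                chain3_system.boundary)

    def test_no_mm_atoms_empty_descriptor(self):
        coords = np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
        st = ffio.Structure(["X", "X"], np.array([91, 91]), coords, set())
        pr = ffio.ForceFieldParams()
        pr.atoms[91] = ("X", 10.0)
        pr.vdw[91] = (3.0, 0.0, 1.0)
        pr.multipoles[91] = ffio.MultipoleRecord(
            0.1, np.zeros(3), np.zeros((3, 3)), "none", ())
        spec = ffio.PartitionSpec({0, 1}, set(), "pseudobond")
        backend = pq.SurrogateBackend(np.array([0.1, 0.1]))
        system = pq.QmmmSystem(st, pr, spec, backend)
        xb = coords_bohr(st)
        gm = mm_energy.rotate_multipoles_to_global(system.electro, xb)
        desc = qmmm.assemble_environment_operators(gm, xb, None,
                                                   system.boundary)
        assert len(desc.site_ids) == 0
        # isolated backend: environment energies vanish
        state, _ = system.energy_and_forces(xb, want_forces=False)
        assert state.e_ele_env == 0.0
        assert state.e_mm == 0.0

    def test_single_mm_charge_coulomb_pair(self):
        """One MM charge next to a surrogate QM charge: the coupling equals
        the bare Coulomb pair energy."""
        coords = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        st = ffio.Structure(["X", "Y"], np.array([91, 92]),
                            coords * units.ANGSTROM_PER_BOHR, set())
        pr = ffio.ForceFieldParams()
        for t, q in ((91, 0.25), (92, -0.4)):
            pr.atoms[t] = ("X", 10.0)
            pr.vdw[t] = (3.0, 0.0, 1.0)
            pr.multipoles[t] = ffio.MultipoleRecord(
                q, np.zeros(3), np.zeros((3, 3)), "none", ())
        spec = ffio.PartitionSpec({0}, set(), "pseudobond")
        system = pq.QmmmSystem(st, pr, spec,
                               pq.SurrogateBackend(np.array([0.25])))
        state, _ = system.energy_and_forces(coords, want_forces=False)
        assert state.e_ele_env == pytest.approx(0.25 * -0.4 / 2.0)


class TestTotalGradient:
    def test_refuses_unconverged_state(self, chain3_system):
        x = coords_bohr(chain3_system.structure)
        state, _ = chain3_system.energy_and_forces(x, want_forces=False)
        state.converged = False
        with pytest.raises(ConvergenceError, match="unconverged"):
            qmmm.total_gradient(state, chain3_system)

    def test_symmetric_dimer_equal_opposite_forces(self):
        coords = np.array([[0.0, 0.0, 0.0], [4.0, 0.0, 0.0]])
        st = ffio.Structure(["X", "X"], np.array([91, 91]),
                            coords * units.ANGSTROM_PER_BOHR, set())
        pr = ffio.ForceFieldParams()
        pr.atoms[91] = ("X", 10.0)
        pr.vdw[91] = (3.4, 0.1, 1.0)
        pr.multipoles[91] = ffio.MultipoleRecord(
            0.3, np.zeros(3), np.zeros((3, 3)), "none", ())
        pr.polarize[91] = (0.6, 0.39, ())
        system = pq.QmmmSystem(st, pr)
        _, F = system.energy_and_forces(coords)
        np.testing.assert_allclose(F[0], -F[1], atol=1e-14)

    def test_forces_match_finite_differences(self, solvated_system, rng):
        st = solvated_system.structure
        x = coords_bohr(st) + 0.02 * rng.standard_normal((st.n_atoms, 3))
        comps = [(0, 1), (4, 0), (5, 2), (10, 1), (30, 0), (46, 2)]
        assert fd_force_check(solvated_system, x, comps) < 1e-7

    def test_decomposition_closure(self, solvated_system):
        state, _ = solvated_system.energy_and_forces(
            coords_bohr(solvated_system.structure), want_forces=False)
        assert state.e_qm_internal + state.e_ele_env + state.e_pol_env \
            + state.e_mm == pytest.approx(state.e_total, abs=1e-12)


class TestEcpSpec:
    def test_defaults_and_validation(self):
        spec = qmmm.EcpSpec("Cps-C", a=1.2, b=0.8)
        assert spec.n_valence_electrons == 7
        with pytest.raises(ValidationError):
            qmmm.EcpSpec("Cps-C", b=-1.0)
        with pytest.raises(ValidationError):
            qmmm.EcpSpec("Cps-C", basis=(1.0, 2.0))

    def test_json_loader(self, tmp_path):
        p = tmp_path / "ecp.json"
        p.write_text('{"Cps-C": {"a": 1.5, "b": 0.9, '
                     '"basis": [0.5, 0.2, 0.7, 0.3]}}')
        table = qmmm.EcpSpec.load(p)
        assert table["Cps-C"].a == 1.5
        assert table["Cps-C"].basis == [0.5, 0.2, 0.7, 0.3]
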