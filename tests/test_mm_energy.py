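"""Classical potential: frames, electrostatics, vdW, valence terms."""

import numpy as np
import pytest

from polqmmm import ffio, fixtures, mm_energy, units
from polqmmm.errors import DegenerateFrameError
from conftest import coords_bohr


def _bare_atomic(n, **kw):
    a = ffio.AtomicMultipoles(
        np.zeros(n), np.zeros((n, 3)), np.zeros((n, 3, 3)), ["none"] * n,
        -np.ones((n, 3), int), np.zeros(n), np.zeros(n), np.arange(n))
    for k, v in kw.items():
        setattr(a, k, v)
    return a


def _free_masks(n):
    one = np.ones((n, n)) - np.eye(n)
    return mm_energy.PairMasks(one, one, one, np.full((n, n), 9))


class TestFrames:
    def test_identity_frame_leaves_multipoles(self):
        a = _bare_atomic(2)
        a.dipole_local[0] = [0.1, 0.2, 0.3]
        gm = mm_energy.rotate_multipoles_to_global(a, np.zeros((2, 3)) + [[0, 0, 0], [1, 0, 0]])
        np.testing.assert_allclose(gm.dipole[0], [0.1, 0.2, 0.3])

    def test_zonly_dipole_follows_axis(self):
        """A local (0,0,d) dipole with the z-axis pointing along +x rotates to
        a global (d,0,0) dipole."""
        a = _bare_atomic(2)
        a.dipole_local[0] = [0.0, 0.0, 0.7]
        a.frame_style[0] = "zonly"
        a.frame_atoms[0, 0] = 1
        coords = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        gm = mm_energy.rotate_multipoles_to_global(a, coords)
        np.testing.assert_allclose(gm.dipole[0], [0.7, 0.0, 0.0], atol=1e-14)

    def test_rotation_matrices_orthonormal(self, water_droplet_small):
        st, pr = water_droplet_small
        a = ffio.assign_atomic_multipoles(st, pr)
        gm = mm_energy.rotate_multipoles_to_global(a, coords_bohr(st))
        eye = np.einsum("nab,ncb->nac", gm.rot, gm.rot)
        np.testing.assert_allclose(eye, np.broadcast_to(np.eye(3), eye.shape),
                                   atol=1e-12)
        # quadrupoles stay traceless under rotation
        assert np.abs(np.trace(gm.quad, axis1=1, axis2=2)).max() < 1e-12

    def test_degenerate_zthenx_frame_rejected(self):
        a = _bare_atomic(3)
        a.dipole_local[0] = [0.1, 0.0, 0.2]
        a.frame_style[0] = "zthenx"
        a.frame_atoms[0, :2] = [1, 2]
        coords = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
        with pytest.raises(DegenerateFrameError):
            mm_energy.rotate_multipoles_to_global(a, coords)

    def test_energy_invariant_under_rigid_rotation(self, water_droplet_small,
                                                   rng):
        """Rotating the whole droplet rigidly leaves the permanent
        electrostatic energy unchanged (frames co-rotate)."""
        st, pr = water_droplet_small
        a = ffio.assign_atomic_multipoles(st, pr)
        masks = mm_energy.build_pair_masks(st, a)
        x = coords_bohr(st)
        gm0 = mm_energy.rotate_multipoles_to_global(a, x)
        e0 = mm_energy.permanent_electrostatics(gm0, x, masks, grad=False).energy
        for _ in range(10):
            q = rng.standard_normal(4)
            q /= np.linalg.norm(q)
            w, xq, yq, zq = q
            R = np.array([
                [1 - 2 * (yq ** 2 + zq ** 2), 2 * (xq * yq - w * zq), 2 * (xq * zq + w * yq)],
                [2 * (xq * yq + w * zq), 1 - 2 * (xq ** 2 + zq ** 2), 2 * (yq * zq - w * xq)],
                [2 * (xq * zq - w * yq), 2 * (yq * zq + w * xq), 1 - 2 * (xq ** 2 + yq ** 2)]])
            xr = x @ R.T + rng.standard_normal(3)
            gm = mm_energy.rotate_multipoles_to_global(a, xr)
            e = mm_energy.permanent_electrostatics(gm, xr, masks,
                                                   grad=False).energy
            assert e == pytest.approx(e0, abs=1e-10)


class TestPermanentElectrostatics:
    def test_two_unit_charges_at_one_bohr(self):
        a = _bare_atomic(2, charge=np.array([1.0, 1.0]))
        gm = mm_energy.rotate_multipoles_to_global(a, np.zeros((2, 3)))
        coords = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        res = mm_energy.permanent_electrostatics(gm, coords, _free_masks(2),
                                                 grad=False)
        assert res.energy == pytest.approx(1.0)

    def test_charge_dipole_closed_form(self):
        """Charge +1 at the origin and a point dipole (0,0,1) at z = 2 bohr:
        E = -q mu / r^2 = -0.25 hartree."""
        a = _bare_atomic(2, charge=np.array([1.0, 0.0]))
        a.dipole_local[1] = [0.0, 0.0, 1.0]
        coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 2.0]])
        gm = mm_energy.rotate_multipoles_to_global(a, coords)
        res = mm_energy.permanent_electrostatics(gm, coords, _free_masks(2),
                                                 grad=False)
        assert res.energy == pytest.approx(-0.25)

    def test_coincident_sites_rejected(self):
        a = _bare_atomic(2, charge=np.array([1.0, 1.0]))
        gm = mm_energy.rotate_multipoles_to_global(a, np.zeros((2, 3)))
        with pytest.raises(ZeroDivisionError):
            mm_energy.permanent_electrostatics(gm, np.zeros((2, 3)),
                                               _free_masks(2))

    def test_matches_point_charge_cluster_oracle(self):
        """Dipoles and quadrupoles represented as vanishing point-charge
        clusters reproduce the analytic multipole-multipole energy
        (Richardson extrapolation of the separation to zero)."""
        cloud = fixtures.make_multipole_cloud(12, seed=4, min_sep=6.0)
        n = len(cloud.charge)
        a = _bare_atomic(n, charge=cloud.charge)
        a.dipole_local[:] = cloud.dipole
        a.quad_local[:] = cloud.quad
        gm = mm_energy.rotate_multipoles_to_global(a, cloud.coords)
        res = mm_energy.permanent_electrostatics(gm, cloud.coords,
                                                 _free_masks(n), grad=False)

        def cluster_energy(delta):
            charges, pos = [], []
            for k in range(n):
                charges.append(cloud.charge[k])
                pos.append(cloud.coords[k])
                p = cloud.dipole[k]
                pn = np.linalg.norm(p)
                if pn > 0:
                    u = p / pn
                    charges += [pn / (2 * delta), -pn / (2 * delta)]
                    pos += [cloud.coords[k] + delta * u,
                            cloud.coords[k] - delta * u]
                # Q = (3/2) * second moment M; realize M = (2/3) Q via
                # +-delta charge pairs along the eigenvectors
                lam, vec = np.linalg.eigh(cloud.quad[k])
                for lmb, v in zip(lam, vec.T):
                    qk = (2.0 / 3.0) * lmb / (2 * delta ** 2)
                    charges += [qk, qk]
                    pos += [cloud.coords[k] + delta * v,
                            cloud.coords[k] - delta * v]
                    charges.append(-2 * qk)
                    pos.append(cloud.coords[k])
            charges = np.array(charges)
            pos = np.array(pos)
            site = np.concatenate([[k] * (1 + (2 if np.linalg.norm(cloud.dipole[k]) > 0 else 0) + 9)
                                   for k in range(n)])
            e = 0.0
            m = len(charges)
            for i in range(m):
                for j in range(i + 1, m):
                    if site[i] == site[j]:
                        continue
                    e += charges[i] * charges[j] / np.linalg.norm(pos[i] - pos[j])
            return e

        e1 = cluster_energy(1e-2)
        e2 = cluster_energy(5e-3)
        extrap = (4 * e2 - e1) / 3.0
        assert extrap == pytest.approx(res.energy, abs=5e-8)


class TestBuffered147:
    def test_depth_at_rmin(self):
        """E(r = r_min) = -eps for the buffered form (the buffering constants
        shift the true stationary point only marginally below rho = 1)."""
        r = np.array([3.5])
        E, dE = mm_energy._b147_kernel(r, np.array([3.5]), np.array([0.1]))
        assert E[0] == pytest.approx(-0.1)
        # derivative magnitude is small near the minimum
        assert abs(dE[0]) < 0.05 * 0.1 / 3.5 * 7

    def test_asymptote_monotone_from_below(self):
        r = np.linspace(4.0, 30.0, 200)
        E, _ = mm_energy._b147_kernel(r, np.full_like(r, 3.5),
                                      np.full_like(r, 0.1))
        assert np.all(E < 0)
        assert np.all(np.diff(E) > 0)
        assert abs(E[-1]) < 1e-6

    def test_gradient_matches_finite_differences(self, water_droplet_small):
        st, pr = water_droplet_small
        vdw = mm_energy.compile_vdw(st, pr)
        a = ffio.assign_atomic_multipoles(st, pr)
        masks = mm_energy.build_pair_masks(st, a)
        x = coords_bohr(st)
        _, g, _ = mm_energy.buffered_14_7(x, vdw, masks)
        h = 1e-4
        for (i, c) in [(0, 0), (1, 2), (5, 1), (9, 0), (11, 2)]:
            xp = x.copy()
            xp[i, c] += h
            xm = x.copy()
            xm[i, c] -= h
            ep = mm_energy.buffered_14_7(xp, vdw, masks)[0]
            em = mm_energy.buffered_14_7(xm, vdw, masks)[0]
            assert (ep - em) / (2 * h) == pytest.approx(g[i, c], abs=1e-8)


class TestValence:
    def test_bond_at_equilibrium_is_zero(self, chain3):
        st, pr, _ = chain3
        topo = ffio.ValenceTopology([(0, 1)], [], [], [], [], [], [])
        cv = mm_energy.compile_valence_terms(st, pr, topo)
        r0 = cv.bond_r0[0]
        x = np.zeros((st.n_atoms, 3))
        x[1, 0] = r0
        e, g, _ = mm_energy.valence_energy(x, cv)
        assert e == pytest.approx(0.0, abs=1e-15)
        assert np.abs(g[:2]).max() < 1e-12

    def test_two_fold_torsion_closed_form(self):
        """A single 2-fold cosine with phase 180: E = (V2/2)(1 - cos 2phi),
        so phi = 90 deg gives exactly V2."""
        st = ffio.Structure(
            ["C"] * 4, np.full(4, 3),
            np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 0.0], [1.0, 0.0, 0.0],
                      [1.0, 0.0, 1.0]]),
            {(0, 1), (1, 2), (2, 3)})
        params = ffio.ForceFieldParams()
        params.bonds[(3, 3)] = (300.0, 1.0)
        params.angles[(3, 3, 3)] = (60.0, 90.0)
        params.torsions[(3, 3, 3, 3)] = [(1.7, 180.0, 2)]
        topo = ffio.ValenceTopology([], [], [], [], [(0, 1, 2, 3)], [], [])
        cv = mm_energy.compile_valence_terms(st, params, topo)
        e, _, dec = mm_energy.valence_energy(coords_bohr(st), cv)
        assert dec["torsion"] == pytest.approx(1.7 * units.HARTREE_PER_KCALMOL)

    def test_valence_gradient_matches_finite_differences(self, chain3, rng):
        st, pr, _ = chain3
        topo = ffio.enumerate_valence_tuples(st, pr)
        cv = mm_energy.compile_valence_terms(st, pr, topo)
        x = coords_bohr(st) + 0.03 * rng.standard_normal((st.n_atoms, 3))
        _, g, _ = mm_energy.valence_energy(x, cv)
        h = 1e-4
        worst = 0.0
        for (i, c) in [(0, 0), (2, 1), (5, 2), (8, 0), (12, 1), (17, 2),
                       (22, 0)]:
            xp = x.copy()
            xp[i, c] += h
            xm = x.copy()
            xm[i, c] -= h
            ep = mm_energy.valence_energy(xp, cv, grad=False)[0]
            em = mm_energy.valence_energy(xm, cv, grad=False)[0]
            worst = max(worst, abs((ep - em) / (2 * h) - g[i, c]))
        assert worst < 1e-8

    def test_unresolvable_tuple_raises_named_error(self, chain3):
        st, pr, _ = chain3
        import copy

        pr2 = copy.deepcopy(pr)
        pr2.bonds.pop(ffio._canon_pair(fixtures.T_N, fixtures.T_CA))
        topo = ffio.enumerate_valence_tuples(st, pr2)
        from polqmmm.errors import ParameterLookupError

        with pytest.raises(ParameterLookupError, match="bond"):
            mm_energy.compile_valence_terms(st, pr2, topo)


class TestInvariances:
    def test_forces_sum_and_torque_vanish(self, solvated_system):
        st = solvated_system.structure
        x = coords_bohr(st)
        state, F = solvated_system.energy_and_forces(x)
        assert np.abs(F.sum(axis=0)).max() < 1e-9
        torque = np.cross(x, F).sum(axis=0)
        assert np.abs(torque).max() < 1e-9

    def test_energy_invariant_under_rigid_motion(self, chain3_system, rng):
        st = chain3_system.structure
        x = coords_bohr(st)
        e0 = chain3_system.energy_and_forces(x, want_forces=False)[0].e_total
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        e1 = chain3_system.energy_and_forces(
            x @ R.T + np.array([3.0, -2.0, 5.0]), want_forces=False)[0].e_total
        assert e1 == pytest.approx(e0, abs=1e-10)
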