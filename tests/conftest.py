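"""Shared fixtures: small deterministic systems reused across the suite."""

import numpy as np
import pytest

import polqmmm as pq
from polqmmm import fixtures, units


@pytest.fixture(scope="session")
def water_droplet_small():
    return fixtures.make_water_droplet(4, seed=3)


@pytest.fixture(scope="session")
def chain3():
    return fixtures.make_pb_chain(3, 2, seed=5)


@pytest.fixture(scope="session")
def chain3_system(chain3):
    st, pr, spec = chain3
    backend = pq.qmmm.surrogate_from_force_field(st, pr, spec.qm_atom_ids)
    return pq.QmmmSystem(st, pr, spec, backend)


@pytest.fixture(scope="session")
def droplet_system(water_droplet_small):
    st, pr = water_droplet_small
    return pq.QmmmSystem(st, pr)


@pytest.fixture(scope="session")
def solvated_system():
    st, pr, spec = fixtures.make_solvated_chain(3, 2, 8, seed=11)
    backend = pq.qmmm.surrogate_from_force_field(st, pr, spec.qm_atom_ids)
    return pq.QmmmSystem(st, pr, spec, backend)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def fd_force_check(system, coords, components, h=1e-4):
    """Central finite differences of E_total against analytic forces."""
    state, F = system.energy_and_forces(coords)
    worst = 0.0
    for i, c in components:
        xp = coords.copy()
        xp[i, c] += h
        xm = coords.copy()
        xm[i, c] -= h
        ep, _ = system.energy_and_forces(xp, want_forces=False)
        em, _ = system.energy_and_forces(xm, want_forces=False)
        fd = -(ep.e_total - em.e_total) / (2 * h)
        worst = max(worst, abs(fd - F[i, c]))
    return worst


def coords_bohr(structure):
    return structure.coords * units.BOHR_PER_ANGSTROM
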