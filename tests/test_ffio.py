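"""Structure/parameter I/O and boundary bookkeeping."""

import numpy as np
import pytest

import polqmmm as pq
from polqmmm import ffio, fixtures
from polqmmm.errors import ParseError, PartitionError, ValidationError

WATER_TXYZ = """\
     3  one water
     1  O    0.000000    0.000000    0.000000    11     2     3
     2  H    0.957200    0.000000    0.000000    12     1
     3  H   -0.239900    0.926800    0.000000    12     1
"""

ASYM_TXYZ = """\
     3  broken water
     1  O    0.000000    0.000000    0.000000    11
     2  H    0.957200    0.000000    0.000000    12     1
     3  H   -0.239900    0.926800    0.000000    12     1
"""


def test_read_minimal_water(tmp_path):
    p = tmp_path / "w.txyz"
    p.write_text(WATER_TXYZ)
    s = ffio.read_tinker_xyz(p)
    assert s.n_atoms == 3
    assert s.bonds == {(0, 1), (0, 2)}
    assert s.elements == ["O", "H", "H"]


def test_asymmetric_connectivity_rejected(tmp_path):
    p = tmp_path / "bad.txyz"
    p.write_text(ASYM_TXYZ)
    with pytest.raises(ValidationError, match="asymmetric"):
        ffio.read_tinker_xyz(p)


def test_malformed_line_reports_line_number(tmp_path):
    p = tmp_path / "bad.txyz"
    p.write_text("     1 x\n     1  O  nan_oops  0.0\n")
    with pytest.raises(ParseError):
        ffio.read_tinker_xyz(p)


def test_txyz_round_trip_droplet(tmp_path):
    st, _ = fixtures.make_water_droplet(50, seed=7)
    p1 = tmp_path / "a.txyz"
    p2 = tmp_path / "b.txyz"
    ffio.write_tinker_xyz(st, p1)
    back = ffio.read_tinker_xyz(p1)
    ffio.write_tinker_xyz(back, p2)
    assert p1.read_text() == p2.read_text()
    assert back.bonds == st.bonds
    np.testing.assert_allclose(back.coords, st.coords, atol=5e-7)


def test_prm_round_trip_water(tmp_path):
    _, params = fixtures.make_water_droplet(1, seed=0)
    p = tmp_path / "water.prm"
    ffio.write_prm(params, p)
    back = ffio.read_prm(p)
    assert len(back.multipoles) == 2
    assert len(back.polarize) == 2
    assert back.multipoles[fixtures.T_OW].frame_style == "bisector"
    np.testing.assert_allclose(
        back.multipoles[fixtures.T_OW].quadrupole,
        params.multipoles[fixtures.T_OW].quadrupole, atol=1e-5)


def test_traced_quadrupole_rejected(tmp_path):
    p = tmp_path / "bad.prm"
    p.write_text("multipole 1 0 0 0.0\n 0.0 0.0 0.0\n 0.1\n 0.0 0.1\n"
                 " 0.0 0.0 0.1\n")
    with pytest.raises(ValidationError, match="traceless"):
        ffio.read_prm(p)


def test_chain_prm_covers_all_valence_terms(chain3, tmp_path):
    """Every valence tuple of the chain topology resolves after a prm
    write/read round trip."""
    st, params, _ = chain3
    p = tmp_path / "chain.prm"
    ffio.write_prm(params, p)
    back = ffio.read_prm(p)
    topo = ffio.enumerate_valence_tuples(st, back)
    from polqmmm import mm_energy

    cv = mm_energy.compile_valence_terms(st, back, topo)  # raises on a hole
    assert len(cv.bond_idx) == len(st.bonds)
    assert len(cv.torsion_idx) > 0
    assert len(cv.pitors_idx) > 0
    assert len(cv.tortors) > 0


def _linear_chain(n, qm, pb):
    """n carbons in a line, unit spacing."""
    coords = np.zeros((n, 3))
    coords[:, 0] = np.arange(n) * 1.5
    bonds = {(i, i + 1) for i in range(n - 1)}
    st = ffio.Structure(["C"] * n, np.full(n, 3), coords, bonds)
    spec = ffio.PartitionSpec(qm_atom_ids=qm, pb_atom_ids=pb)
    return st, spec


def test_partition_minimal_chain():
    # q1-q2-PB-m1-m2
    st, spec = _linear_chain(5, {0, 1, 2}, {2})
    bm = ffio.build_partition(st, spec)
    assert bm.mm1 == {2: [3]}
    assert bm.mm2 == {3: [4]}


def test_partition_pb_without_mm_neighbour_rejected():
    st, spec = _linear_chain(5, {0, 1, 2, 3, 4}, {2})
    with pytest.raises(PartitionError, match="no MM neighbour"):
        ffio.build_partition(st, spec)


def test_partition_bonded_pb_atoms_rejected():
    st, spec = _linear_chain(6, {0, 1, 2, 3}, {2, 3})
    with pytest.raises(PartitionError, match="bonded to each other"):
        ffio.build_partition(st, spec)


def test_partition_undeclared_crossing_bond_rejected():
    st, spec = _linear_chain(5, {0, 1}, set())
    spec.scheme = "pseudobond"
    with pytest.raises(PartitionError, match="not declared"):
        ffio.build_partition(st, spec)


def test_pb_type_carbonyl_classification():
    """An alanine-like cut at the alpha carbon next to the amide carbonyl is
    classified as Cps-C=O."""
    st, pr, spec = fixtures.make_pb_chain(3, 2, seed=1, qm_side="c")
    bm = ffio.build_partition(st, spec)
    assert list(bm.pb_types.values()) == ["Cps-C=O"]
    st2, _, spec2 = fixtures.make_pb_chain(3, 2, seed=1, qm_side="n")
    bm2 = ffio.build_partition(st2, spec2)
    assert list(bm2.pb_types.values()) == ["Cps-N"]


def test_branched_mm2_order_stable():
    # star: PB(0)-m1(1); m1 bonded to m2a(2), m2b(3)
    coords = np.array([[0, 0, 0], [1.5, 0, 0], [2.5, 1, 0], [2.5, -1, 0],
                       [-1.5, 0, 0]], dtype=float)
    st = ffio.Structure(["C"] * 5, np.full(5, 3), coords,
                        {(0, 1), (1, 2), (1, 3), (0, 4)})
    spec = ffio.PartitionSpec({0, 4}, {0})
    bm = ffio.build_partition(st, spec)
    assert bm.mm2[1] == [2, 3]  # deterministic, index-sorted


def test_zero_and_redistribute_conserves_charge(chain3):
    st, params, spec = chain3
    bm = ffio.build_partition(st, spec)
    atomic = ffio.assign_atomic_multipoles(st, params)
    adjusted = ffio.zero_and_redistribute(atomic, bm)
    assert adjusted.total_charge() == pytest.approx(atomic.total_charge(),
                                                    abs=1e-14)
    for p in bm.pb_atoms:
        assert adjusted.charge[p] == 0.0
        assert adjusted.alpha[p] == 0.0
        for m1 in bm.mm1[p]:
            assert adjusted.charge[m1] == 0.0
            assert np.all(adjusted.dipole_local[m1] == 0.0)
            assert np.all(adjusted.quad_local[m1] == 0.0)
            assert adjusted.alpha[m1] == 0.0
            share = atomic.charge[m1] / len(bm.mm2[m1])
            for b in bm.mm2[m1]:
                assert adjusted.charge[b] == pytest.approx(
                    atomic.charge[b] + share)


def test_zero_charge_mm1_still_zeroed():
    st, params, spec = fixtures.make_pb_chain(3, 2, seed=5)
    bm = ffio.build_partition(st, spec)
    atomic = ffio.assign_atomic_multipoles(st, params)
    m1 = bm.mm1[bm.pb_atoms[0]][0]
    atomic.charge[m1] = 0.0
    before = atomic.copy()
    adjusted = ffio.zero_and_redistribute(atomic, bm)
    for b in bm.mm2[m1]:
        assert adjusted.charge[b] == before.charge[b]
    assert np.all(adjusted.dipole_local[m1] == 0.0)
    assert adjusted.alpha[m1] == 0.0


def test_redistribute_without_mm2_fails():
    # PB(0)-m1(1) terminal: nowhere to put m1's charge
    coords = np.array([[0, 0, 0], [1.5, 0, 0], [-1.5, 0, 0]], dtype=float)
    st = ffio.Structure(["C", "C", "C"], np.full(3, 3), coords,
                        {(0, 1), (0, 2)})
    spec = ffio.PartitionSpec({0, 2}, {0})
    bm = ffio.build_partition(st, spec)
    atomic = ffio.AtomicMultipoles(
        np.array([0.0, -0.1, 0.1]), np.zeros((3, 3)), np.zeros((3, 3, 3)),
        ["none"] * 3, -np.ones((3, 3), int), np.zeros(3), np.zeros(3),
        np.arange(3))
    with pytest.raises(PartitionError, match="cannot be redistributed"):
        ffio.zero_and_redistribute(atomic, bm)


def test_hybrid_terms_minimal_chain():
    """Chain q2-PB-m1-m2: the hybrid list is exactly the PB-m1 stretch, the
    two boundary angles and the single spanning torsion."""
    st, _ = _linear_chain(4, {0, 1}, {1})
    bm = ffio.build_partition(st, ffio.PartitionSpec({0, 1}, {1}))
    hybrid, mm, qm = ffio.enumerate_boundary_valence_terms(st, bm)
    assert hybrid.bonds == [(1, 2)]
    assert hybrid.angles == [(0, 1, 2), (1, 2, 3)]
    assert hybrid.torsions == [(0, 1, 2, 3)]
    assert qm.bonds == [(0, 1)]
    assert mm.bonds == [(2, 3)]


def test_no_pb_atoms_empty_hybrid(water_droplet_small):
    st, _ = water_droplet_small
    bm = ffio.build_partition(st, ffio.PartitionSpec(set(), set(), "none"))
    hybrid, mm, qm = ffio.enumerate_boundary_valence_terms(st, bm)
    assert all(not getattr(hybrid, f) for f in
               ("bonds", "angles", "torsions", "pitors", "tortors"))
    assert len(mm.bonds) == len(st.bonds)


def test_term_partition_is_exact(chain3):
    """hybrid + pure-MM + pure-QM tuples partition the uncut tuple set, with
    no tuple in two lists (brute-force set oracle)."""
    st, params, spec = chain3
    bm = ffio.build_partition(st, spec)
    full = ffio.enumerate_valence_tuples(st, params)
    hybrid, mm, qm = ffio.enumerate_boundary_valence_terms(st, bm, params)
    for f in ("bonds", "angles", "strbnd", "opbend", "torsions", "pitors",
              "tortors"):
        h, m, q = (set(getattr(x, f)) for x in (hybrid, mm, qm))
        assert h | m | q == set(getattr(full, f))
        assert not (h & m) and not (h & q) and not (m & q)


def test_link_atom_capping_geometry_and_charges(chain3):
    st, params, spec = chain3
    spec_link = ffio.PartitionSpec(spec.qm_atom_ids, set(), "link_atom",
                                   link_scale=0.72)
    atomic = ffio.assign_atomic_multipoles(st, params)
    capped, adjusted, links = ffio.build_link_atom_capping(
        st, spec_link, atomic, scale=0.72)
    assert len(links) == 1
    a, b, pos = links[0]
    vec = st.coords[b] - st.coords[a]
    np.testing.assert_allclose(pos, st.coords[a] + 0.72 * vec)
    # hydrogen placed at scale * |AB|
    assert np.linalg.norm(pos - st.coords[a]) == pytest.approx(
        0.72 * np.linalg.norm(vec))
    # replaced MM atom stripped; charge moved to its classical neighbours
    assert adjusted.charge[b] == 0.0
    assert adjusted.total_charge() == pytest.approx(atomic.total_charge(),
                                                    abs=1e-14)
    assert capped.elements[-1] == "H"
    assert capped.n_atoms == len(spec.qm_atom_ids) + 1


def test_link_atom_equal_split():
    coords = np.array([[0, 0, 0], [1.5, 0, 0], [2.5, 1, 0], [2.5, -1, 0],
                       [3.5, 0, 0]], dtype=float)
    st = ffio.Structure(["C"] * 5, np.full(5, 3), coords,
                        {(0, 1), (1, 2), (1, 3), (1, 4)})
    spec = ffio.PartitionSpec({0}, set(), "link_atom")
    atomic = ffio.AtomicMultipoles(
        np.array([0.0, -0.12, 0.0, 0.0, 0.0]), np.zeros((5, 3)),
        np.zeros((5, 3, 3)), ["none"] * 5, -np.ones((5, 3), int),
        np.zeros(5), np.zeros(5), np.arange(5))
    _, adjusted, _ = ffio.build_link_atom_capping(st, spec, atomic)
    assert adjusted.charge[2] == pytest.approx(-0.04)
    assert adjusted.charge[3] == pytest.approx(-0.04)
    assert adjusted.charge[4] == pytest.approx(-0.04)
    assert adjusted.total_charge() == pytest.approx(-0.12)


def test_link_atom_nonpositive_scale_rejected(chain3):
    st, params, spec = chain3
    atomic = ffio.assign_atomic_multipoles(st, params)
    spec_link = ffio.PartitionSpec(spec.qm_atom_ids, set(), "link_atom")
    with pytest.raises(ValidationError):
        ffio.build_link_atom_capping(st, spec_link, atomic, scale=0.0)


def test_partition_config_json(tmp_path):
    p = tmp_path / "part.json"
    p.write_text('{"qm_atoms": [1, 2, 3], "pb_atoms": [3], '
                 '"scheme": "pseudobond", "link_scale": 0.7}')
    spec = ffio.load_partition_config(p)
    assert spec.qm_atom_ids == {0, 1, 2}
    assert spec.pb_atom_ids == {2}
    assert spec.link_scale == 0.7
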