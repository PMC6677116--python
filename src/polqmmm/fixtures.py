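"""Deterministic test-input generators.

Everything the test-suite and the examples consume is generated here: rigid
water droplets, peptide-like chains with designated pseudobond cuts, random
multipole/polarizability clouds and synthetic transition-density fields.  The
parameters are AMOEBA-like in *form* (multipoles through quadrupoles, Thole
polarizabilities, buffered 14-7, full valence coverage including pi-torsions
and a torsion-torsion map) but synthetic in *value*: no real force-field file
is distributed, while real prm files remain loadable through
:func:`polqmmm.ffio.read_prm`.

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import units
from .errors import PolQmmmError
from .ffio import (
    ForceFieldParams,
    MultipoleRecord,
    PartitionSpec,
    Structure,
    _canon_pair,
    _canon_quad,
    _canon_triple,
    enumerate_valence_tuples,
)

__all__ = [
    "make_water_droplet",
    "make_pb_chain",
    "make_solvated_chain",
    "make_multipole_cloud",
    "make_transition_fields",
    "MultipoleCloud",
    "surrogate_site_model",
    "merge",
]

# type ids: chain 1..8, water 11..12
T_N, T_HN, T_CA, T_HA, T_C, T_O, T_HC = 1, 2, 3, 4, 5, 6, 7
T_OW, T_HW = 11, 12

_WATER_OH = 0.9572
_WATER_ANGLE = 104.52


def _water_params() -> ForceFieldParams:
    p = ForceFieldParams()
    p.atoms[T_OW] = ("O", 15.999)
    p.atoms[T_HW] = ("H", 1.008)
    p.vdw[T_OW] = (3.405, 0.11, 1.0)
    p.vdw[T_HW] = (2.655, 0.0135, 0.91)
    p.bonds[(T_OW, T_HW)] = (556.85, _WATER_OH)
    p.angles[_canon_triple(T_HW, T_OW, T_HW)] = (48.70, _WATER_ANGLE)
    p.multipoles[T_OW] = MultipoleRecord(
        -0.52, np.array([0.0, 0.0, 0.075]),
        np.array([[0.10, 0.0, 0.0], [0.0, -0.12, 0.0], [0.0, 0.0, 0.02]]),
        "bisector", (T_HW, T_HW))
    p.multipoles[T_HW] = MultipoleRecord(
        0.26, np.array([0.0, 0.0, -0.020]),
        np.array([[-0.01, 0.0, 0.0], [0.0, -0.01, 0.0], [0.0, 0.0, 0.02]]),
        "zthenx", (T_OW, T_HW))
    p.polarize[T_OW] = (0.837, 0.39, (T_HW,))
    p.polarize[T_HW] = (0.496, 0.39, (T_OW,))
    return p


def _water_geometry():
    """One rigid water in its local frame (O at origin, bisector along -z)."""
    th = math.radians(_WATER_ANGLE / 2.0)
    h1 = np.array([math.sin(th), 0.0, math.cos(th)]) * _WATER_OH
    h2 = np.array([-math.sin(th), 0.0, math.cos(th)]) * _WATER_OH
    return np.array([[0.0, 0.0, 0.0], h1, h2])


def _random_rotation(rng):
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def make_water_droplet(n_waters, radius=None, seed=0, min_oo=2.8,
                       avoid=None, avoid_dist=2.6):
    """Randomly placed and oriented rigid waters inside a sphere (Angstrom).

    Minimum O-O distance ``min_oo`` is enforced by rejection sampling; the
    optional ``avoid`` coordinate set (a solute) is kept at ``avoid_dist``.
    Raises after bounded attempts when the packing is infeasible.
    """
    if n_waters < 1:
        raise PolQmmmError("need at least one water")
    rng = np.random.default_rng(seed)
    if radius is None:
        radius = max(3.0, (n_waters / 0.016) ** (1.0 / 3.0))
    base = _water_geometry()
    oxygens = []
    coords = []
    attempts = 0
    while len(oxygens) < n_waters:
        attempts += 1
        if attempts > 2000 * n_waters:
            raise PolQmmmError(
                f"could not pack {n_waters} waters in radius {radius:.1f} A")
        pos = rng.uniform(-radius, radius, 3)
        if np.linalg.norm(pos) > radius:
            continue
        if oxygens and np.min(np.linalg.norm(np.array(oxygens) - pos, axis=1)) < min_oo:
            continue
        if avoid is not None and np.min(
                np.linalg.norm(np.asarray(avoid) - pos, axis=1)) < avoid_dist:
            continue
        R = _random_rotation(rng)
        mol = pos + base @ R.T
        oxygens.append(pos)
        coords.append(mol)
    coords = np.concatenate(coords)
    elements, tids, bonds = [], [], set()
    for w in range(n_waters):
        o = 3 * w
        elements += ["O", "H", "H"]
        tids += [T_OW, T_HW, T_HW]
        bonds.add((o, o + 1))
        bonds.add((o, o + 2))
    struct = Structure(elements, np.array(tids), coords, bonds,
                       title=f"{n_waters}-water droplet (seed {seed})")
    return struct, _water_params()


# ---------------------------------------------------------------------------
# Peptide-like chain with pseudobond cuts
# ---------------------------------------------------------------------------

def _place(a, b, c, r, theta_deg, phi_deg):
    """Place a point bonded to c at distance r, angle (b,c,.)=theta and
    dihedral (a,b,c,.)=phi."""
    theta = math.radians(theta_deg)
    phi = math.radians(phi_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-r * math.cos(theta),
                  r * math.sin(theta) * math.cos(phi),
                  r * math.sin(theta) * math.sin(phi)])
    return c + d[0] * bc + d[1] * m + d[2] * n


_BOND_REF = {
    _canon_pair(T_N, T_HN): (460.0, 1.01),
    _canon_pair(T_N, T_CA): (350.0, 1.45),
    _canon_pair(T_CA, T_HA): (340.0, 1.09),
    _canon_pair(T_CA, T_C): (320.0, 1.51),
    _canon_pair(T_C, T_O): (570.0, 1.23),
    _canon_pair(T_C, T_N): (430.0, 1.35),
    _canon_pair(T_C, T_HC): (340.0, 1.10),
}

_SP2_CENTRES = {T_N, T_C}


def _chain_params(structure: Structure) -> ForceFieldParams:
    """Synthetic amide-chain parameters with guaranteed full valence coverage,
    generated from the actual topology."""
    p = ForceFieldParams()
    p.atoms.update({
        T_N: ("N", 14.007), T_HN: ("H", 1.008), T_CA: ("C", 12.011),
        T_HA: ("H", 1.008), T_C: ("C", 12.011), T_O: ("O", 15.999),
        T_HC: ("H", 1.008),
    })
    p.vdw.update({
        T_N: (3.71, 0.105, 1.0), T_HN: (2.59, 0.022, 0.90),
        T_CA: (3.82, 0.101, 1.0), T_HA: (2.88, 0.024, 0.91),
        T_C: (3.82, 0.106, 1.0), T_O: (3.30, 0.112, 1.0),
        T_HC: (2.88, 0.024, 0.91),
    })
    p.bonds.update(_BOND_REF)
    charges = {T_N: -0.35, T_HN: 0.17, T_CA: 0.0, T_HA: 0.09,
               T_C: 0.55, T_O: -0.55, T_HC: 0.06}
    dip = {T_N: 0.04, T_HN: -0.01, T_CA: 0.02, T_HA: -0.01,
           T_C: 0.10, T_O: -0.08, T_HC: 0.0}
    quad = {T_N: 0.25, T_CA: 0.10, T_C: 0.30, T_O: 0.40,
            T_HN: 0.02, T_HA: 0.02, T_HC: 0.02}
    frames = {
        T_N: ("zthenx", (T_C, T_CA)), T_HN: ("zonly", (T_N,)),
        T_CA: ("zthenx", (T_N, T_C)), T_HA: ("zonly", (T_CA,)),
        T_C: ("zthenx", (T_O, T_N)), T_O: ("zonly", (T_C,)),
        T_HC: ("zonly", (T_C,)),
    }
    for t, q in charges.items():
        qq = quad[t]
        style, ftypes = frames[t]
        p.multipoles[t] = MultipoleRecord(
            q, np.array([0.0, 0.0, dip[t]]),
            np.diag([0.5 * qq, 0.5 * qq, -qq]) * -1.0, style, ftypes)
    neighbours = {
        T_N: (T_HN, T_CA, T_C), T_HN: (T_N,), T_CA: (T_N, T_HA, T_C),
        T_HA: (T_CA,), T_C: (T_CA, T_O, T_N, T_HC), T_O: (T_C,),
        T_HC: (T_C,),
    }
    alphas = {T_N: 1.073, T_HN: 0.496, T_CA: 1.334, T_HA: 0.496,
              T_C: 1.334, T_O: 0.837, T_HC: 0.496}
    for t, a in alphas.items():
        p.polarize[t] = (a, 0.39, neighbours[t])

    # generated valence coverage from the topology
    topo = enumerate_valence_tuples(structure)
    tids = structure.type_ids
    adj = structure.neighbors
    for (i, j, k) in topo.angles:
        key = _canon_triple(int(tids[i]), int(tids[j]), int(tids[k]))
        if key in p.angles:
            continue
        centre = int(tids[j])
        sp2 = centre in _SP2_CENTRES and len(adj[j]) == 3
        theta0 = 120.0 if sp2 else 109.47
        p.angles[key] = (62.0, theta0)
        heavy = {T_N, T_CA, T_C, T_O}
        if {key[0], key[2]} <= heavy:
            p.strbnd.setdefault(key, (4.5, 4.5))
    for (a, d, b, c) in topo.opbend:
        if int(tids[d]) in _SP2_CENTRES:
            p.opbend.setdefault((int(tids[a]), int(tids[d]), 0, 0), 11.0)
    for tup in topo.torsions:
        key = _canon_quad([int(tids[x]) for x in tup])
        if key in p.torsions:
            continue
        central = _canon_pair(key[1], key[2])
        if central == _canon_pair(T_C, T_N):
            p.torsions[key] = [(2.0, 180.0, 2)]
        elif key[1] in _SP2_CENTRES or key[2] in _SP2_CENTRES:
            p.torsions[key] = [(0.6, 180.0, 2), (0.15, 0.0, 3)]
        else:
            p.torsions[key] = [(0.30, 0.0, 3)]
    p.pitors[_canon_pair(T_C, T_N)] = 6.85

    # torsion-torsion map on the N-CA-C-N-CA backbone path
    ang = np.arange(-180.0, 181.0, 30.0)
    phi, psi = np.meshgrid(np.radians(ang), np.radians(ang), indexing="ij")
    grid = (0.12 * np.cos(phi) + 0.08 * np.cos(2.0 * psi)
            + 0.05 * np.cos(phi + psi))
    p.tortors[(T_N, T_CA, T_C, T_N, T_CA)] = (ang.copy(), ang.copy(), grid)
    return p


def make_pb_chain(n_units, cut_index, seed=0, qm_side="n"):
    """Amide-backbone chain H2N-[CH2-C(=O)-NH]n-H with a pseudobond cut.

    Unit ``u`` contributes N, HN, CA, 2xHA, C, O; the chain is capped with an
    extra N-terminal hydrogen and a C-terminal aldehyde-like hydrogen.  The
    cut replaces the alpha-carbon CA of unit ``cut_index`` (1-based) by the PB
    atom: the QM region holds units 1..cut_index up to and including that CA
    and its hydrogens; MM1 = {C of the cut unit} carries charge +0.55 so the
    redistribution onto MM2 = {O, next N} is exercised.

    Returns (structure, params, partition_spec).
    """
    if not (0 < cut_index < n_units):
        raise PolQmmmError("cut_index must satisfy 0 < cut_index < n_units")
    rng = np.random.default_rng(seed)
    jit = lambda: rng.uniform(-8.0, 8.0)  # noqa: E731

    elements, tids, coords, bonds = [], [], [], set()
    index = {}

    def add(label, element, tid, pos, bond_to=()):
        idx = len(elements)
        index[label] = idx
        elements.append(element)
        tids.append(tid)
        coords.append(np.asarray(pos, dtype=float))
        for b in bond_to:
            bonds.add(tuple(sorted((idx, index[b]))))
        return idx

    r_NC = _BOND_REF[_canon_pair(T_N, T_CA)][1]
    r_CC = _BOND_REF[_canon_pair(T_CA, T_C)][1]
    r_CN = _BOND_REF[_canon_pair(T_C, T_N)][1]
    r_CO = _BOND_REF[_canon_pair(T_C, T_O)][1]
    r_NH = _BOND_REF[_canon_pair(T_N, T_HN)][1]
    r_CH = _BOND_REF[_canon_pair(T_CA, T_HA)][1]

    add("N1", "N", T_N, [0.0, 0.0, 0.0])
    add("CA1", "C", T_CA, [r_NC, 0.0, 0.0], ("N1",))
    add("C1", "C", T_C,
        _place(np.array([0.0, 0.0, 1.0]), coords[index["N1"]],
               coords[index["CA1"]], r_CC, 111.0, 120.0 + jit()),
        ("CA1",))
    for u in range(2, n_units + 1):
        cp, cap, npv = index[f"C{u-1}"], index[f"CA{u-1}"], index[f"N{u-1}"]
        add(f"N{u}", "N", T_N,
            _place(coords[npv], coords[cap], coords[cp], r_CN, 116.0,
                   150.0 + jit()), (f"C{u-1}",))
        add(f"CA{u}", "C", T_CA,
            _place(coords[cap], coords[cp], coords[index[f"N{u}"]], r_NC,
                   122.0, 180.0), (f"N{u}",))
        add(f"C{u}", "C", T_C,
            _place(coords[cp], coords[index[f"N{u}"]],
                   coords[index[f"CA{u}"]], r_CC, 111.0, -120.0 + jit()),
            (f"CA{u}",))
    # substituents
    for u in range(1, n_units + 1):
        N, CA, C = index[f"N{u}"], index[f"CA{u}"], index[f"C{u}"]
        ref = index[f"C{u-1}"] if u > 1 else C
        add(f"HN{u}", "H", T_HN,
            _place(coords[CA], coords[ref] if u > 1 else coords[C],
                   coords[N], r_NH, 118.0, 180.0), (f"N{u}",))
        if u == 1:
            add("HN1b", "H", T_HN,
                _place(coords[C], coords[CA], coords[N], r_NH, 118.0, 65.0),
                ("N1",))
        add(f"HA{u}a", "H", T_HA,
            _place(coords[N], coords[C], coords[CA], r_CH, 108.0, 118.0),
            (f"CA{u}",))
        add(f"HA{u}b", "H", T_HA,
            _place(coords[N], coords[C], coords[CA], r_CH, 108.0, -118.0),
            (f"CA{u}",))
        add(f"O{u}", "O", T_O,
            _place(coords[N], coords[CA], coords[C], r_CO, 121.0,
                   180.0 if u < n_units else 150.0), (f"C{u}",))
        if u == n_units:
            add(f"HC{u}", "H", T_HC,
                _place(coords[N], coords[CA], coords[C], r_CH, 115.0, -30.0),
                (f"C{u}",))

    structure = Structure(elements, np.array(tids), np.array(coords), bonds,
                          title=f"{n_units}-unit amide chain (seed {seed})")
    params = _chain_params(structure)

    cut = cut_index
    qm = set()
    if qm_side == "n":
        # QM region = N-terminal side up to and including CA(cut) = PB
        for u in range(1, cut + 1):
            qm.update(index[f"{lbl}{u}"] for lbl in ("N", "HN"))
            if u == 1:
                qm.add(index["HN1b"])
            if u < cut:
                qm.update(index[f"{lbl}{u}"] for lbl in ("CA", "C", "O"))
                qm.update((index[f"HA{u}a"], index[f"HA{u}b"]))
        qm.update((index[f"CA{cut}"], index[f"HA{cut}a"], index[f"HA{cut}b"]))
    elif qm_side == "c":
        # QM region = C-terminal side: PB CA(cut) sees the carbonyl carbon of
        # its own unit on the QM side (Cps-C=O boundary class)
        for u in range(cut, n_units + 1):
            qm.update(index[f"{lbl}{u}"] for lbl in ("C", "O"))
            if u > cut:
                qm.update(index[f"{lbl}{u}"] for lbl in ("N", "HN", "CA"))
                qm.update((index[f"HA{u}a"], index[f"HA{u}b"]))
            if u == n_units:
                qm.add(index[f"HC{u}"])
        qm.update((index[f"CA{cut}"], index[f"HA{cut}a"], index[f"HA{cut}b"]))
    else:
        raise PolQmmmError("qm_side must be 'n' or 'c'")
    spec = PartitionSpec(qm_atom_ids=qm, pb_atom_ids={index[f"CA{cut}"]},
                         scheme="pseudobond")
    return structure, params, spec


def make_pb_chain_two_cuts(n_units, cut_lo, cut_hi, seed=0):
    """Chain with an interior QM region bounded by two pseudobond atoms
    (CA of units ``cut_lo`` and ``cut_hi``), mirroring a hexapeptide with a
    boundary on each flanking residue."""
    if not (0 < cut_lo < cut_hi <= n_units):
        raise PolQmmmError("need 0 < cut_lo < cut_hi <= n_units")
    structure, params, _ = make_pb_chain(n_units, cut_lo, seed=seed)
    # atom labels follow a fixed construction order; rebuild the index
    index = {}
    pos = 0
    for u in range(1, n_units + 1):
        index[f"N{u}"] = pos
        index[f"CA{u}"] = pos + 1
        index[f"C{u}"] = pos + 2
        pos += 3
    for u in range(1, n_units + 1):
        index[f"HN{u}"] = pos
        pos += 1
        if u == 1:
            index["HN1b"] = pos
            pos += 1
        index[f"HA{u}a"] = pos
        index[f"HA{u}b"] = pos + 1
        index[f"O{u}"] = pos + 2
        pos += 3
        if u == n_units:
            index[f"HC{u}"] = pos
            pos += 1
    qm = {index[f"CA{cut_lo}"], index[f"HA{cut_lo}a"], index[f"HA{cut_lo}b"],
          index[f"C{cut_lo}"], index[f"O{cut_lo}"],
          index[f"CA{cut_hi}"], index[f"HA{cut_hi}a"], index[f"HA{cut_hi}b"],
          index[f"N{cut_hi}"], index[f"HN{cut_hi}"]}
    for u in range(cut_lo + 1, cut_hi):
        qm.update(index[f"{lbl}{u}"] for lbl in ("N", "HN", "CA", "C", "O"))
        qm.update((index[f"HA{u}a"], index[f"HA{u}b"]))
    spec = PartitionSpec(
        qm_atom_ids=qm,
        pb_atom_ids={index[f"CA{cut_lo}"], index[f"CA{cut_hi}"]},
        scheme="pseudobond")
    return structure, params, spec


def merge(struct_a: Structure, params_a: ForceFieldParams,
          struct_b: Structure, params_b: ForceFieldParams):
    """Concatenate two structures and union their parameter tables (type id
    sets must be disjoint)."""
    overlap = set(params_a.atoms) & set(params_b.atoms)
    if overlap:
        raise PolQmmmError(f"type id collision on merge: {sorted(overlap)}")
    off = struct_a.n_atoms
    elements = list(struct_a.elements) + list(struct_b.elements)
    tids = np.concatenate([struct_a.type_ids, struct_b.type_ids])
    coords = np.vstack([struct_a.coords, struct_b.coords])
    bonds = set(struct_a.bonds) | {(i + off, j + off) for i, j in struct_b.bonds}
    merged = Structure(elements, tids, coords, bonds,
                       title=(struct_a.title + " + " + struct_b.title))
    params = ForceFieldParams()
    for field_name in ("atoms", "multipoles", "polarize", "vdw", "bonds",
                       "angles", "strbnd", "opbend", "torsions", "pitors",
                       "tortors", "scalars"):
        d = dict(getattr(params_a, field_name))
        d.update(getattr(params_b, field_name))
        setattr(params, field_name, d)
    return merged, params


def make_solvated_chain(n_units, cut_index, n_waters, seed=0, radius=None):
    """A pseudobond-cut amide chain solvated in a droplet of fixture water.

    Returns (structure, params, partition_spec) with the chain first.
    """
    chain, cp, spec = make_pb_chain(n_units, cut_index, seed=seed)
    centred = chain.copy()
    centred.coords = centred.coords - centred.coords.mean(axis=0)
    if radius is None:
        radius = max(6.0, (n_waters / 0.012) ** (1.0 / 3.0))
    wat, wp = make_water_droplet(n_waters, radius=radius, seed=seed + 1,
                                 avoid=centred.coords, avoid_dist=3.0)
    merged, params = merge(centred, cp, wat, wp)
    return merged, params, spec


# ---------------------------------------------------------------------------
# Random multipole clouds and synthetic fields
# ---------------------------------------------------------------------------

@dataclass
class MultipoleCloud:
    """Random global-frame multipole sites (atomic units)."""

    coords: np.ndarray      # (n, 3) bohr
    charge: np.ndarray
    dipole: np.ndarray      # (n, 3) e*bohr
    quad: np.ndarray        # (n, 3, 3) internal convention, traceless
    alpha: np.ndarray       # (n,) bohr^3
    thole: np.ndarray


def make_multipole_cloud(n, seed=0, box=None, min_sep=4.0) -> MultipoleCloud:
    """Neutralized random charges, dipoles, traceless quadrupoles and
    polarizabilities with a minimum separation (bohr)."""
    if n < 2:
        raise PolQmmmError("need at least two sites")
    rng = np.random.default_rng(seed)
    if box is None:
        box = max(8.0, 2.2 * min_sep * n ** (1.0 / 3.0))
    pts = []
    attempts = 0
    while len(pts) < n:
        attempts += 1
        if attempts > 5000 * n:
            raise PolQmmmError("could not place cloud sites")
        x = rng.uniform(-box / 2, box / 2, 3)
        if pts and np.min(np.linalg.norm(np.array(pts) - x, axis=1)) < min_sep:
            continue
        pts.append(x)
    coords = np.array(pts)
    q = rng.uniform(-0.5, 0.5, n)
    q -= q.mean()
    dip = rng.uniform(-0.3, 0.3, (n, 3))
    quad = rng.uniform(-0.3, 0.3, (n, 3, 3))
    quad = 0.5 * (quad + np.transpose(quad, (0, 2, 1)))
    tr = np.trace(quad, axis1=1, axis2=2) / 3.0
    quad -= tr[:, None, None] * np.eye(3)
    alpha = rng.uniform(2.0, 8.0, n)
    thole = np.full(n, 0.39)
    return MultipoleCloud(coords, q, dip, quad, alpha, thole)


def make_transition_fields(n_sites, seed=0, scale=5e-3):
    """Synthetic transition-density fields at polarizable sites (a.u.)."""
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n_sites, 3)) * scale


def surrogate_site_model(structure: Structure, params: ForceFieldParams,
                         qm_atoms, polarizable=True):
    """Charges/alphas for a surrogate backend taken from the classical
    monopoles and polarizabilities of the QM atoms (the natural stand-in)."""
    qm_sorted = sorted(qm_atoms)
    charges, alphas = [], []
    for a in qm_sorted:
        tid = int(structure.type_ids[a])
        rec = params.multipoles.get(tid)
        charges.append(rec.charge if rec else 0.0)
        pol = params.polarize.get(tid)
        alphas.append(pol[0] * units.BOHR_PER_ANGSTROM ** 3
                      if (pol and polarizable) else 0.0)
    return np.array(charges), np.array(alphas)
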