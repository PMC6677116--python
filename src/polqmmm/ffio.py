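"""Structures, force-field parameters and QM/MM partition bookkeeping.

Reads/writes Tinker-style Cartesian files with connectivity (txyz) and a subset
of Tinker parameter files (prm), builds the bonded graph, and prepares
pseudobond (PB) and link-atom QM/MM boundaries:

* atoms classically bonded to a PB atom (MM1) lose their permanent multipoles
  and polarizabilities, and their monopole charge is moved, split equally, onto
  the next shell of classical atoms (MM2), so the total charge is conserved
  exactly;
* valence terms that straddle the boundary (containing at least one MM atom and
  at least one QM-or-PB atom) are enumerated as *hybrid* terms, evaluated with
  the classical force field, including the PB-MM1 stretch;
* alternatively a hydrogen link atom can cap each cut bond, with the replaced
  MM atom's charge redistributed over its classical neighbours.

Structure coordinates are kept in Angstrom (the file unit); per-atom
electrostatic parameters produced by :func:`assign_atomic_multipoles` are in
atomic units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import units
from .errors import (
    ParseError,
    PartitionError,
    ValidationError,
)

__all__ = [
    "Structure",
    "ForceFieldParams",
    "MultipoleRecord",
    "PartitionSpec",
    "BoundaryMap",
    "AtomicMultipoles",
    "ValenceTopology",
    "read_tinker_xyz",
    "write_tinker_xyz",
    "read_prm",
    "load_partition_config",
    "build_partition",
    "assign_atomic_multipoles",
    "zero_and_redistribute",
    "enumerate_valence_tuples",
    "enumerate_boundary_valence_terms",
    "build_link_atom_capping",
]

QUADRUPOLE_TRACE_TOL = 1e-6


# ---------------------------------------------------------------------------
# Structure
# ---------------------------------------------------------------------------

@dataclass
class Structure:
    """Atoms with element symbols, force-field type ids, coordinates (Angstrom)
    and symmetric connectivity."""

    elements: list
    type_ids: np.ndarray
    coords: np.ndarray
    bonds: set  # of 2-tuples (i, j) with i < j, 0-based
    title: str = ""

    def __post_init__(self):
        self.type_ids = np.asarray(self.type_ids, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.bonds = {tuple(sorted(b)) for b in self.bonds}
        n = self.n_atoms
        for i, j in self.bonds:
            if i == j:
                raise ValidationError(f"self-bond on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValidationError(f"bond ({i},{j}) references invalid atom index")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def neighbors(self) -> dict:
        """Adjacency map {atom: sorted list of bonded atoms}."""
        adj = {i: [] for i in range(self.n_atoms)}
        for i, j in self.bonds:
            adj[i].append(j)
            adj[j].append(i)
        return {i: sorted(v) for i, v in adj.items()}

    def copy(self) -> "Structure":
        return Structure(
            list(self.elements),
            self.type_ids.copy(),
            self.coords.copy(),
            set(self.bonds),
            self.title,
        )


def read_tinker_xyz(path) -> Structure:
    """Read a Tinker txyz file (index, symbol, x, y, z, type, neighbour list).

    Connectivity must be symmetric: if atom a lists b, atom b must list a.
    """
    with open(path) as fh:
        lines = fh.readlines()
    if not lines:
        raise ParseError("empty file", path=path, line=1)
    head = lines[0].split()
    try:
        n_atoms = int(head[0])
    except (IndexError, ValueError):
        raise ParseError("first line must give the atom count", path=path, line=1)
    title = " ".join(head[1:])
    if len(lines) < n_atoms + 1:
        raise ParseError(
            f"expected {n_atoms} atom lines, found {len(lines) - 1}", path=path,
            line=len(lines))

    elements, type_ids, coords = [], [], []
    neigh = []
    for ln in range(1, n_atoms + 1):
        toks = lines[ln].split()
        if len(toks) < 6:
            raise ParseError("atom line needs index, symbol, x, y, z, type",
                             path=path, line=ln + 1)
        try:
            idx = int(toks[0])
            x, y, z = float(toks[2]), float(toks[3]), float(toks[4])
            tid = int(toks[5])
            nb = [int(t) - 1 for t in toks[6:]]
        except ValueError as exc:
            raise ParseError(f"malformed field ({exc})", path=path, line=ln + 1)
        if idx != ln:
            raise ParseError(f"atom index {idx} out of order", path=path, line=ln + 1)
        elements.append(toks[1])
        coords.append((x, y, z))
        type_ids.append(tid)
        neigh.append(nb)

    bonds = set()
    for i, nbrs in enumerate(neigh):
        for j in nbrs:
            if not 0 <= j < n_atoms:
                raise ParseError(f"atom {i + 1} lists neighbour {j + 1} out of range",
                                 path=path, line=i + 2)
            bonds.add(tuple(sorted((i, j))))
    # symmetry check
    for i, j in sorted(bonds):
        if j not in neigh[i] or i not in neigh[j]:
            raise ValidationError(
                f"asymmetric connectivity between atoms {i + 1} and {j + 1} in {path}")
    return Structure(elements, np.array(type_ids), np.array(coords), bonds, title)


def write_tinker_xyz(structure: Structure, path) -> None:
    """Write a txyz file; coordinates with 6 decimals (round-trip stable)."""
    adj = structure.neighbors
    with open(path, "w") as fh:
        fh.write(f"{structure.n_atoms:6d}  {structure.title}\n")
        for i in range(structure.n_atoms):
            x, y, z = structure.coords[i]
            nb = "".join(f"{j + 1:6d}" for j in adj[i])
            fh.write(f"{i + 1:6d}  {structure.elements[i]:<3s}"
                     f"{x:12.6f}{y:12.6f}{z:12.6f}{structure.type_ids[i]:6d}{nb}\n")


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class MultipoleRecord:
    """Permanent multipoles of one atom type, in its local frame (file units:
    e, e*Ang, e*Ang^2 with Stone's traceless-quadrupole convention)."""

    charge: float
    dipole: np.ndarray          # (3,)
    quadrupole: np.ndarray      # (3, 3), traceless
    frame_style: str            # none | zonly | zthenx | bisector | zbisector
    frame_types: tuple          # defining neighbour types (absolute values)


@dataclass
class ForceFieldParams:
    """Typed parameter tables for the AMOEBA-style potential (file units)."""

    atoms: dict = field(default_factory=dict)       # type -> (element, mass_amu)
    multipoles: dict = field(default_factory=dict)  # type -> MultipoleRecord
    polarize: dict = field(default_factory=dict)    # type -> (alpha_A3, thole, group_types)
    vdw: dict = field(default_factory=dict)         # type -> (rmin_A, eps_kcal, reduction)
    bonds: dict = field(default_factory=dict)       # (t1,t2) -> (k, r0)
    angles: dict = field(default_factory=dict)      # (t1,t2,t3) -> (k, theta0_deg)
    strbnd: dict = field(default_factory=dict)      # (t1,t2,t3) -> (k1, k2)
    opbend: dict = field(default_factory=dict)      # (t_out,t_center,tb,tc) -> k
    torsions: dict = field(default_factory=dict)    # (t1..t4) -> [(V, phase_deg, n)]
    pitors: dict = field(default_factory=dict)      # (t1,t2) -> k
    tortors: dict = field(default_factory=dict)     # (t1..t5) -> (ang1, ang2, grid)
    scalars: dict = field(default_factory=dict)     # global keywords

    # anharmonicity defaults (per-Angstrom / per-radian polynomial coefficients)
    @property
    def bond_cubic(self):
        return self.scalars.get("bond-cubic", -2.55)

    @property
    def bond_quartic(self):
        return self.scalars.get("bond-quartic", 3.793125)

    @property
    def angle_coeffs(self):
        """Higher-order angle coefficients (cubic..sextic), per radian powers."""
        return (
            self.scalars.get("angle-cubic", -0.014 * units.DEG_PER_RAD),
            self.scalars.get("angle-quartic", 5.6e-5 * units.DEG_PER_RAD ** 2),
            self.scalars.get("angle-pentic", -7.0e-7 * units.DEG_PER_RAD ** 3),
            self.scalars.get("angle-sextic", 2.2e-8 * units.DEG_PER_RAD ** 4),
        )


def _canon_pair(t1, t2):
    return (t1, t2) if t1 <= t2 else (t2, t1)


def _canon_triple(t1, t2, t3):
    return (t1, t2, t3) if t1 <= t3 else (t3, t2, t1)


def _canon_quad(ts):
    return tuple(ts) if tuple(ts) <= tuple(reversed(ts)) else tuple(reversed(ts))


def read_prm(path) -> ForceFieldParams:
    """Parse a Tinker-keyword parameter file subset.

    Recognized records: atom, vdw, bond, angle, strbnd, opbend, torsion,
    pitors, tortors, multipole, polarize, and scalar keywords (bond-cubic,
    angle-cubic, ...).  Unknown keywords are skipped.
    """
    params = ForceFieldParams()
    with open(path) as fh:
        lines = fh.readlines()

    i = 0
    while i < len(lines):
        raw = lines[i]
        toks = raw.split()
        i += 1
        if not toks or toks[0].startswith("#"):
            continue
        key = toks[0].lower()
        try:
            if key == "atom":
                # atom  type  element  mass
                tid = int(toks[1])
                params.atoms[tid] = (toks[2], float(toks[3]))
            elif key == "vdw":
                tid = int(toks[1])
                red = float(toks[4]) if len(toks) > 4 else 1.0
                params.vdw[tid] = (float(toks[2]), float(toks[3]), red)
            elif key == "bond":
                params.bonds[_canon_pair(int(toks[1]), int(toks[2]))] = (
                    float(toks[3]), float(toks[4]))
            elif key == "angle":
                params.angles[_canon_triple(int(toks[1]), int(toks[2]), int(toks[3]))] = (
                    float(toks[4]), float(toks[5]))
            elif key == "strbnd":
                params.strbnd[_canon_triple(int(toks[1]), int(toks[2]), int(toks[3]))] = (
                    float(toks[4]), float(toks[5]))
            elif key == "opbend":
                ta, td, tb, tc = (int(toks[1]), int(toks[2]), int(toks[3]), int(toks[4]))
                params.opbend[(ta, td) + _canon_pair(tb, tc)] = float(toks[5])
            elif key == "torsion":
                tt = _canon_quad([int(t) for t in toks[1:5]])
                terms = []
                rest = toks[5:]
                for k in range(0, len(rest) - 2, 3):
                    terms.append((float(rest[k]), float(rest[k + 1]), int(rest[k + 2])))
                params.torsions[tt] = terms
            elif key == "pitors":
                params.pitors[_canon_pair(int(toks[1]), int(toks[2]))] = float(toks[3])
            elif key == "tortors":
                t5 = tuple(int(t) for t in toks[1:6])
                nx, ny = int(toks[6]), int(toks[7])
                pts = []
                while len(pts) < nx * ny:
                    sub = lines[i].split()
                    i += 1
                    pts.append((float(sub[0]), float(sub[1]), float(sub[2])))
                ang1 = sorted({p[0] for p in pts})
                ang2 = sorted({p[1] for p in pts})
                grid = np.full((len(ang1), len(ang2)), np.nan)
                for a1, a2, v in pts:
                    grid[ang1.index(a1), ang2.index(a2)] = v
                if np.isnan(grid).any():
                    raise ParseError("incomplete torsion-torsion grid",
                                     path=path, line=i)
                params.tortors[t5] = (np.array(ang1, float), np.array(ang2, float), grid)
            elif key == "multipole":
                tid = int(toks[1])
                frame_raw = [int(t) for t in toks[2:-1]]
                q = float(toks[-1])
                if len(lines) < i + 4:
                    raise ParseError("multipole block truncated", path=path, line=i)
                try:
                    d = [float(x) for x in lines[i].split()]
                    qxx = [float(x) for x in lines[i + 1].split()]
                    qxy = [float(x) for x in lines[i + 2].split()]
                    qxz = [float(x) for x in lines[i + 3].split()]
                    if len(d) != 3 or len(qxx) != 1 or len(qxy) != 2 or len(qxz) != 3:
                        raise ValueError("wrong line shape")
                except ValueError as exc:
                    raise ParseError(f"multipole block with wrong line count ({exc})",
                                     path=path, line=i + 1)
                i += 4
                quad = np.array([
                    [qxx[0], qxy[0], qxz[0]],
                    [qxy[0], qxy[1], qxz[1]],
                    [qxz[0], qxz[1], qxz[2]],
                ])
                tr = abs(np.trace(quad))
                if tr > QUADRUPOLE_TRACE_TOL:
                    raise ValidationError(
                        f"quadrupole of type {tid} has trace {np.trace(quad):.3g} "
                        f"(must be traceless)")
                style, ftypes = _frame_from_ints(frame_raw)
                params.multipoles[tid] = MultipoleRecord(
                    q, np.array(d, float), quad, style, ftypes)
            elif key == "polarize":
                tid = int(toks[1])
                alpha = float(toks[2])
                thole = float(toks[3])
                group = tuple(int(t) for t in toks[4:])
                params.polarize[tid] = (alpha, thole, group)
            elif key in ("bond-cubic", "bond-quartic", "angle-cubic", "angle-quartic",
                         "angle-pentic", "angle-sextic"):
                params.scalars[key] = float(toks[1])
            # unknown keywords silently skipped
        except (IndexError, ValueError) as exc:
            raise ParseError(f"malformed '{key}' record ({exc})", path=path, line=i)
    return params


def write_prm(params: ForceFieldParams, path) -> None:
    """Write the parameter tables as Tinker-keyword records."""
    with open(path, "w") as fh:
        for tid, (el, mass) in sorted(params.atoms.items()):
            fh.write(f"atom {tid} {el} {mass:.4f}\n")
        for key, val in sorted(params.scalars.items()):
            fh.write(f"{key} {val}\n")
        for tid, (r, e, red) in sorted(params.vdw.items()):
            fh.write(f"vdw {tid} {r:.4f} {e:.5f}"
                     + (f" {red:.3f}\n" if red != 1.0 else "\n"))
        for (t1, t2), (k, r0) in sorted(params.bonds.items()):
            fh.write(f"bond {t1} {t2} {k:.2f} {r0:.4f}\n")
        for key, (k, t0) in sorted(params.angles.items()):
            fh.write(f"angle {key[0]} {key[1]} {key[2]} {k:.2f} {t0:.2f}\n")
        for key, (k1, k2) in sorted(params.strbnd.items()):
            fh.write(f"strbnd {key[0]} {key[1]} {key[2]} {k1:.3f} {k2:.3f}\n")
        for key, k in sorted(params.opbend.items()):
            fh.write(f"opbend {key[0]} {key[1]} {key[2]} {key[3]} {k:.3f}\n")
        for key, terms in sorted(params.torsions.items()):
            rec = " ".join(f"{v:.3f} {g:.1f} {n}" for v, g, n in terms)
            fh.write(f"torsion {key[0]} {key[1]} {key[2]} {key[3]} {rec}\n")
        for (t1, t2), k in sorted(params.pitors.items()):
            fh.write(f"pitors {t1} {t2} {k:.3f}\n")
        for key, (a1, a2, grid) in sorted(params.tortors.items()):
            fh.write(f"tortors {key[0]} {key[1]} {key[2]} {key[3]} {key[4]} "
                     f"{len(a1)} {len(a2)}\n")
            for i1, x1 in enumerate(a1):
                for i2, x2 in enumerate(a2):
                    fh.write(f" {x1:.1f} {x2:.1f} {grid[i1, i2]:.6f}\n")
        for tid, rec in sorted(params.multipoles.items()):
            frame = _frame_to_ints(rec)
            fh.write(f"multipole {tid} " + " ".join(str(f) for f in frame)
                     + f" {rec.charge:.5f}\n")
            d = rec.dipole
            Q = rec.quadrupole
            fh.write(f" {d[0]:.5f} {d[1]:.5f} {d[2]:.5f}\n")
            fh.write(f" {Q[0, 0]:.5f}\n")
            fh.write(f" {Q[0, 1]:.5f} {Q[1, 1]:.5f}\n")
            fh.write(f" {Q[0, 2]:.5f} {Q[1, 2]:.5f} {Q[2, 2]:.5f}\n")
        for tid, (alpha, thole, group) in sorted(params.polarize.items()):
            fh.write(f"polarize {tid} {alpha:.4f} {thole:.3f} "
                     + " ".join(str(g) for g in group) + "\n")


def _frame_to_ints(rec: MultipoleRecord):
    ft = rec.frame_types
    if rec.frame_style == "none":
        return (0, 0)
    if rec.frame_style == "zonly":
        return (ft[0], 0)
    if rec.frame_style == "zthenx":
        return (ft[0], ft[1])
    if rec.frame_style == "bisector":
        return (-ft[0], -ft[1])
    return (ft[0], -ft[1], -ft[2])  # zbisector


def _frame_from_ints(frame_raw):
    """Map Tinker multipole frame integers to (style, abs type tuple)."""
    vals = list(frame_raw)
    if not vals or vals[0] == 0:
        return "none", ()
    if len(vals) == 1 or (len(vals) >= 2 and vals[1] == 0):
        return "zonly", (abs(vals[0]),)
    if len(vals) == 2:
        kz, kx = vals
        if kz < 0 and kx < 0:
            return "bisector", (abs(kz), abs(kx))
        return "zthenx", (kz, kx)
    kz, kx, ky = vals[:3]
    if kz > 0 and kx < 0 and ky < 0:
        return "zbisector", (kz, abs(kx), abs(ky))
    return "zthenx", (abs(kz), abs(kx))


# ---------------------------------------------------------------------------
# Partition
# ---------------------------------------------------------------------------

@dataclass
class PartitionSpec:
    """Names the QM atoms and the pseudobond atoms among them."""

    qm_atom_ids: set
    pb_atom_ids: set = field(default_factory=set)
    scheme: str = "pseudobond"   # pseudobond | link_atom | none
    link_scale: float = 0.71

    def __post_init__(self):
        self.qm_atom_ids = set(int(i) for i in self.qm_atom_ids)
        self.pb_atom_ids = set(int(i) for i in self.pb_atom_ids)
        if self.scheme not in ("pseudobond", "link_atom", "none"):
            raise ValidationError(f"unknown partition scheme '{self.scheme}'")
        if not self.pb_atom_ids <= self.qm_atom_ids:
            raise ValidationError("pb_atom_ids must be a subset of qm_atom_ids")


def load_partition_config(path) -> PartitionSpec:
    """Load a JSON partition config with keys qm_atoms, pb_atoms, scheme,
    link_scale (atom ids 1-based on file)."""
    with open(path) as fh:
        cfg = json.load(fh)
    return PartitionSpec(
        qm_atom_ids={i - 1 for i in cfg["qm_atoms"]},
        pb_atom_ids={i - 1 for i in cfg.get("pb_atoms", [])},
        scheme=cfg.get("scheme", "pseudobond"),
        link_scale=cfg.get("link_scale", 0.71),
    )


@dataclass
class BoundaryMap:
    """QM/PB/MM1/MM2 classification derived from a partition."""

    qm_atoms: set                 # includes PB atoms
    pb_atoms: list                # sorted PB atom ids
    mm1: dict                     # pb -> sorted list of MM1 atoms
    mm2: dict                     # mm1_atom -> sorted list of MM2 atoms
    pb_types: dict                # pb -> label ("Cps-C", "Cps-N", "Cps-C=O")
    scheme: str = "pseudobond"

    @property
    def mm_atoms_of(self):
        raise AttributeError

    def all_mm1(self):
        out = set()
        for v in self.mm1.values():
            out.update(v)
        return out

    def all_mm2(self):
        out = set()
        for v in self.mm2.values():
            out.update(v)
        return out


def _classify_pb_type(structure: Structure, pb: int, qm_atoms: set) -> str:
    """Label the pseudobond from the QM-side bonded neighbour: carbon -> Cps-C,
    carbonyl carbon (C with a single-bonded O) -> Cps-C=O, nitrogen -> Cps-N."""
    adj = structure.neighbors
    qm_neigh = [a for a in adj[pb] if a in qm_atoms and a != pb]
    if not qm_neigh:
        raise PartitionError(f"PB atom {pb} has no QM neighbour")
    heavy = [a for a in qm_neigh
             if not structure.elements[a].upper().startswith("H")]
    a = heavy[0] if heavy else qm_neigh[0]
    el = structure.elements[a].upper()[:1]
    if el == "N":
        return "Cps-N"
    if el == "C":
        for b in adj[a]:
            if structure.elements[b].upper().startswith("O") and len(adj[b]) == 1:
                return "Cps-C=O"
        return "Cps-C"
    return f"Cps-{structure.elements[a]}"


def build_partition(structure: Structure, spec: PartitionSpec) -> BoundaryMap:
    """Derive the MM1/MM2 shells and pseudobond classification for a partition.

    MM1 = MM atoms bonded to each PB atom; MM2 = MM atoms bonded to an MM1
    (excluding the PB atom itself).
    """
    qm = set(spec.qm_atom_ids)
    adj = structure.neighbors
    if spec.scheme == "none":
        return BoundaryMap(qm, [], {}, {}, {}, scheme="none")

    pb_sorted = sorted(spec.pb_atom_ids)
    for p in pb_sorted:
        for q in adj[p]:
            if q in spec.pb_atom_ids:
                raise PartitionError(
                    f"PB atoms {p} and {q} are bonded to each other (unsupported)")

    mm1, mm2, pb_types = {}, {}, {}
    for p in pb_sorted:
        m1 = sorted(a for a in adj[p] if a not in qm)
        if not m1:
            raise PartitionError(
                f"PB atom {p} has no MM neighbour: not a valid boundary cut")
        if not any(a in qm for a in adj[p]):
            raise PartitionError(f"PB atom {p} has no QM neighbour")
        mm1[p] = m1
        for a in m1:
            mm2[a] = sorted(b for b in adj[a] if b not in qm and b != a and b not in m1)
        pb_types[p] = _classify_pb_type(structure, p, qm)
    # pseudobond runs must route every cut through a declared PB atom
    # (link-atom cuts are capped instead)
    if spec.scheme == "pseudobond":
        for i, j in structure.bonds:
            i_in, j_in = i in qm, j in qm
            if i_in != j_in:
                pb_side = i if i_in else j
                if pb_side not in spec.pb_atom_ids:
                    raise PartitionError(
                        f"bond ({i},{j}) crosses the QM/MM boundary but atom "
                        f"{pb_side} is not declared as a PB atom")
    return BoundaryMap(qm, pb_sorted, mm1, mm2, pb_types, scheme=spec.scheme)


# ---------------------------------------------------------------------------
# Per-atom electrostatics (atomic units) and boundary adjustment
# ---------------------------------------------------------------------------

@dataclass
class AtomicMultipoles:
    """Per-atom electrostatic parameters in atomic units.

    ``dipole_local``/``quad_local`` are in the local multipole frame; the
    internal quadrupole convention is V(r) = Q:ss/r^5 (Stone values are halved
    on conversion).  ``frame_atoms`` holds the resolved frame-defining atom
    indices (-1 padding).
    """

    charge: np.ndarray        # (n,) e
    dipole_local: np.ndarray  # (n, 3) e*bohr
    quad_local: np.ndarray    # (n, 3, 3) e*bohr^2, internal convention
    frame_style: list         # per atom
    frame_atoms: np.ndarray   # (n, 3) int, -1 = unused
    alpha: np.ndarray         # (n,) bohr^3
    thole: np.ndarray         # (n,)
    group_id: np.ndarray      # (n,) polarization group labels

    def copy(self) -> "AtomicMultipoles":
        return AtomicMultipoles(
            self.charge.copy(), self.dipole_local.copy(), self.quad_local.copy(),
            list(self.frame_style), self.frame_atoms.copy(), self.alpha.copy(),
            self.thole.copy(), self.group_id.copy())

    @property
    def n_sites(self):
        return len(self.charge)

    def total_charge(self) -> float:
        return float(self.charge.sum())


def _resolve_frame_atoms(structure, i, rec):
    """Pick bonded neighbours matching the frame-defining types, deterministic
    by atom index."""
    adj = structure.neighbors[i]
    tids = structure.type_ids
    chosen, used = [], set()
    for ft in rec.frame_types:
        cand = [a for a in adj if tids[a] == ft and a not in used]
        if not cand:
            # fall back to 1-3 neighbours (Tinker allows the x atom there)
            cand = [b for a in adj for b in structure.neighbors[a]
                    if b != i and tids[b] == ft and b not in used]
        if not cand:
            raise ValidationError(
                f"atom {i} (type {tids[i]}): no neighbour of type {ft} to define "
                f"the '{rec.frame_style}' multipole frame")
        chosen.append(min(cand))
        used.add(min(cand))
    return chosen


def assign_atomic_multipoles(structure: Structure,
                             params: ForceFieldParams) -> AtomicMultipoles:
    """Expand the per-type multipole/polarize tables into per-atom arrays
    (atomic units) with resolved frame atoms and polarization groups."""
    n = structure.n_atoms
    q = np.zeros(n)
    d = np.zeros((n, 3))
    Q = np.zeros((n, 3, 3))
    styles = ["none"] * n
    fatoms = -np.ones((n, 3), dtype=int)
    alpha = np.zeros(n)
    thole = np.zeros(n)

    A = units.BOHR_PER_ANGSTROM
    for i in range(n):
        tid = int(structure.type_ids[i])
        rec = params.multipoles.get(tid)
        if rec is not None:
            q[i] = rec.charge
            d[i] = rec.dipole * A  # e*Ang -> e*bohr
            Q[i] = 0.5 * rec.quadrupole * A ** 2  # Stone e*Ang^2 -> internal e*bohr^2
            styles[i] = rec.frame_style
            if rec.frame_style != "none":
                fa = _resolve_frame_atoms(structure, i, rec)
                fatoms[i, :len(fa)] = fa
        pol = params.polarize.get(tid)
        if pol is not None:
            alpha[i] = pol[0] * A ** 3  # Ang^3 -> bohr^3
            thole[i] = pol[1]

    group_id = _polarization_groups(structure, params)
    return AtomicMultipoles(q, d, Q, styles, fatoms, alpha, thole, group_id)


def _polarization_groups(structure, params):
    """Connected components over bonds whose endpoint types appear in each
    other's polarize group list."""
    n = structure.n_atoms
    tids = structure.type_ids
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in structure.bonds:
        gi = params.polarize.get(int(tids[i]), (0, 0, ()))[2]
        gj = params.polarize.get(int(tids[j]), (0, 0, ()))[2]
        if tids[j] in gi or tids[i] in gj:
            parent[find(i)] = find(j)
    return np.array([find(i) for i in range(n)])


def zero_and_redistribute(atomic: AtomicMultipoles,
                          boundary_map: BoundaryMap) -> AtomicMultipoles:
    """Boundary electrostatic bookkeeping for the pseudobond scheme.

    MM1 multipoles and polarizabilities are set to zero and each MM1 monopole
    is split equally over that MM1's MM2 neighbours, so the classical charge
    moved is conserved exactly.  PB atoms carry no classical multipoles or
    polarizabilities: their classical representation is vacated (it lives in
    the QM nuclear/electronic description instead).
    """
    adj = atomic.copy()
    for p in boundary_map.pb_atoms:
        adj.charge[p] = 0.0
        adj.dipole_local[p] = 0.0
        adj.quad_local[p] = 0.0
        adj.alpha[p] = 0.0
        adj.frame_style[p] = "none"
        adj.frame_atoms[p] = -1
        for m1 in boundary_map.mm1[p]:
            m2 = boundary_map.mm2[m1]
            if not m2:
                raise PartitionError(
                    f"MM1 atom {m1} has no MM2 neighbour: its charge "
                    f"{atomic.charge[m1]:+.4f} cannot be redistributed")
            share = atomic.charge[m1] / len(m2)
            for b in m2:
                adj.charge[b] += share
            adj.charge[m1] = 0.0
            adj.dipole_local[m1] = 0.0
            adj.quad_local[m1] = 0.0
            adj.alpha[m1] = 0.0
            adj.frame_style[m1] = "none"
            adj.frame_atoms[m1] = -1
    return adj


# ---------------------------------------------------------------------------
# Valence tuple enumeration and hybrid-term bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class ValenceTopology:
    """All valence term tuples of a bonded graph (canonical order, sorted)."""

    bonds: list
    angles: list
    strbnd: list
    opbend: list       # (out_atom, center, b, c)
    torsions: list
    pitors: list       # (a, b, c1, d1, c2, d2): central bond a-b + substituents
    tortors: list      # 5-atom paths


def enumerate_valence_tuples(structure: Structure,
                             params: Optional[ForceFieldParams] = None
                             ) -> ValenceTopology:
    """Enumerate every bond/angle/stretch-bend/out-of-plane/torsion/pi-torsion/
    torsion-torsion tuple of the bonded graph.

    With ``params`` given, the *optional* term classes (strbnd, opbend, pitors,
    tortors) are restricted to tuples with a parameter record; bonds, angles
    and torsions are always enumerated (a missing mandatory record surfaces
    later as a ParameterLookupError).
    """
    adj = structure.neighbors
    tids = structure.type_ids

    bonds = sorted(structure.bonds)
    angles = []
    for j in range(structure.n_atoms):
        nb = adj[j]
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                i, k = nb[a], nb[b]
                angles.append((i, j, k) if i < k else (k, j, i))
    angles.sort()

    torsions = []
    for (j, k) in bonds:
        for i in adj[j]:
            if i == k:
                continue
            for l in adj[k]:
                if l == j or l == i:
                    continue
                t = (i, j, k, l)
                if t[::-1] < t:
                    t = t[::-1]
                torsions.append(t)
    torsions = sorted(set(torsions))

    # out-of-plane: trigonal centres, one term per out-of-plane bond
    opbend = []
    for d in range(structure.n_atoms):
        nb = adj[d]
        if len(nb) != 3:
            continue
        for a in nb:
            b, c = sorted(x for x in nb if x != a)
            opbend.append((a, d, b, c))
    opbend.sort()

    # pi-torsions: bonds between two trigonal centres
    pitors = []
    for (a, b) in bonds:
        na = [x for x in adj[a] if x != b]
        nbb = [x for x in adj[b] if x != a]
        if len(na) == 2 and len(nbb) == 2:
            pitors.append((a, b, na[0], na[1], nbb[0], nbb[1]))
    pitors.sort()

    # torsion-torsion: 5-atom simple paths
    seen = set()
    for t in torsions:
        i, j, k, l = t
        for m in adj[l]:
            if m not in (i, j, k):
                p = (i, j, k, l, m)
                if p[::-1] < p:
                    p = p[::-1]
                seen.add(p)
        for m in adj[i]:
            if m not in (j, k, l):
                p = (m, i, j, k, l)
                if p[::-1] < p:
                    p = p[::-1]
                seen.add(p)
    tortors = sorted(seen)

    strbnd = list(angles)

    if params is not None:
        strbnd = [a for a in strbnd
                  if _canon_triple(*(int(tids[x]) for x in a)) in params.strbnd]
        opbend = [o for o in opbend if _lookup_opbend_key(tids, o, params) is not None]
        pitors = [p for p in pitors
                  if _canon_pair(int(tids[p[0]]), int(tids[p[1]])) in params.pitors]
        tortors = [p for p in tortors
                   if _lookup_tortor_key(tids, p, params) is not None]
    return ValenceTopology(bonds, angles, strbnd, opbend, torsions, pitors, tortors)


def _lookup_opbend_key(tids, tup, params):
    a, d, b, c = tup
    key = (int(tids[a]), int(tids[d])) + _canon_pair(int(tids[b]), int(tids[c]))
    if key in params.opbend:
        return key
    wild = (int(tids[a]), int(tids[d]), 0, 0)
    if wild in params.opbend:
        return wild
    return None


def _lookup_tortor_key(tids, path, params):
    key = tuple(int(tids[x]) for x in path)
    if key in params.tortors:
        return key
    rkey = key[::-1]
    if rkey in params.tortors:
        return rkey
    return None


def _term_atom_sets(topo: ValenceTopology):
    """Yield (kind, tuple, atoms-involved) for every term."""
    for b in topo.bonds:
        yield "bond", b, b
    for a in topo.angles:
        yield "angle", a, a
    for a in topo.strbnd:
        yield "strbnd", a, a
    for o in topo.opbend:
        yield "opbend", o, o
    for t in topo.torsions:
        yield "torsion", t, t
    for p in topo.pitors:
        yield "pitors", p, p
    for p in topo.tortors:
        yield "tortors", p, p


def enumerate_boundary_valence_terms(structure: Structure,
                                     boundary_map: BoundaryMap,
                                     params: Optional[ForceFieldParams] = None):
    """Split all valence tuples into (hybrid, pure_mm, pure_qm) ValenceTopology
    triples.

    A tuple is *hybrid* when it contains at least one MM atom and at least one
    atom from QM ∪ PB (this includes the PB-MM1 stretch); tuples fully inside
    QM belong to the electronic-structure backend and tuples fully inside MM to
    the pure-MM potential.
    """
    topo = enumerate_valence_tuples(structure, params)
    qm = boundary_map.qm_atoms  # includes PB atoms

    def split(tuples):
        hybrid, mm, qml = [], [], []
        for t in tuples:
            inside = sum(1 for a in t if a in qm)
            if inside == 0:
                mm.append(t)
            elif inside == len(t):
                qml.append(t)
            else:
                hybrid.append(t)
        return hybrid, mm, qml

    fields = ["bonds", "angles", "strbnd", "opbend", "torsions", "pitors", "tortors"]
    hy, mm, qml = {}, {}, {}
    for f in fields:
        hy[f], mm[f], qml[f] = split(getattr(topo, f))
    if boundary_map.scheme == "none" and not boundary_map.qm_atoms:
        hy = {f: [] for f in fields}
    return (ValenceTopology(**hy), ValenceTopology(**mm), ValenceTopology(**qml))


# ---------------------------------------------------------------------------
# Link-atom capping
# ---------------------------------------------------------------------------

def build_link_atom_capping(structure: Structure, spec: PartitionSpec,
                            atomic: AtomicMultipoles, scale: Optional[float] = None):
    """Cap each cut QM-MM bond with a hydrogen and redistribute the replaced
    MM atom's charge.

    The hydrogen sits on the A-B axis at ``scale * |AB|`` from the QM-side
    atom.  The replaced MM boundary atom's monopole is split equally over its
    bonded classical neighbours, its higher multipoles and polarizability are
    dropped, and it is removed as a classical source; total charge is
    conserved.

    Returns ``(capped_structure, adjusted, link_atoms)`` where
    ``capped_structure`` contains the QM atoms plus link hydrogens,
    ``adjusted`` is the boundary-adjusted :class:`AtomicMultipoles` on the
    original atom list, and ``link_atoms`` records (qm_atom, replaced_mm_atom,
    position).
    """
    if scale is None:
        scale = spec.link_scale
    if scale <= 0:
        raise ValidationError(f"link-atom scale must be positive, got {scale}")
    qm = set(spec.qm_atom_ids)
    adj_map = structure.neighbors
    cut_bonds = [(i, j) for (i, j) in sorted(structure.bonds)
                 if (i in qm) != (j in qm)]

    adjusted = atomic.copy()
    link_atoms = []
    replaced = sorted({(j if i in qm else i) for i, j in cut_bonds})
    for mm_atom in replaced:
        neighbors = [a for a in adj_map[mm_atom] if a not in qm]
        if not neighbors:
            raise PartitionError(
                f"replaced MM atom {mm_atom} has no classical neighbour to "
                f"receive its charge")
        share = atomic.charge[mm_atom] / len(neighbors)
        for a in neighbors:
            adjusted.charge[a] += share
        adjusted.charge[mm_atom] = 0.0
        adjusted.dipole_local[mm_atom] = 0.0
        adjusted.quad_local[mm_atom] = 0.0
        adjusted.alpha[mm_atom] = 0.0
        adjusted.frame_style[mm_atom] = "none"
        adjusted.frame_atoms[mm_atom] = -1

    qm_sorted = sorted(qm)
    index_map = {a: k for k, a in enumerate(qm_sorted)}
    elements = [structure.elements[a] for a in qm_sorted]
    tids = [int(structure.type_ids[a]) for a in qm_sorted]
    coords = [structure.coords[a] for a in qm_sorted]
    bonds = {(index_map[i], index_map[j]) for (i, j) in structure.bonds
             if i in qm and j in qm}
    for (i, j) in cut_bonds:
        a, b = (i, j) if i in qm else (j, i)  # a: QM side, b: MM side
        vec = structure.coords[b] - structure.coords[a]
        pos = structure.coords[a] + scale * vec
        elements.append("H")
        tids.append(0)
        coords.append(pos)
        bonds.add(tuple(sorted((index_map[a], len(elements) - 1))))
        link_atoms.append((a, b, pos))
    capped = Structure(elements, np.array(tids), np.array(coords), bonds,
                       title=structure.title + " (link-atom capped)")
    return capped, adjusted, link_atoms
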