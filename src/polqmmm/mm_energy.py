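"""Classical AMOEBA-style potential: permanent multipole electrostatics,
buffered 14-7 van der Waals, and valence terms, with exact gradients.

Nonbonded gradients are analytic (interaction-tensor contractions, see
``_kernels``).  Valence-term gradients and the local-frame rotation chain rule
(the force contributions arising because global dipoles/quadrupoles rotate
with the molecular frame) are evaluated by complex-step differentiation, which
is exact to machine precision.

All public functions work in atomic units (bohr/hartree); parameter
compilation converts from the file units (Angstrom, kcal/mol, degrees).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.interpolate import RectBivariateSpline

from . import units
from ._kernels import buffered_14_7 as _b147_kernel
from ._kernels import pair_multipole_energy
from .errors import DegenerateFrameError, ParameterLookupError
from .ffio import (
    AtomicMultipoles,
    ForceFieldParams,
    Structure,
    ValenceTopology,
    _canon_pair,
    _canon_quad,
    _canon_triple,
    _lookup_opbend_key,
    _lookup_tortor_key,
)

_CSTEP = 1e-20  # complex-step size; error is O(h^2) in exact arithmetic


# ---------------------------------------------------------------------------
# Local-frame rotation
# ---------------------------------------------------------------------------

@dataclass
class GlobalMultipoles:
    """Per-site multipoles rotated into the global frame (atomic units)."""

    charge: np.ndarray
    dipole: np.ndarray      # (n, 3)
    quad: np.ndarray        # (n, 3, 3)
    rot: np.ndarray         # (n, 3, 3), columns = global images of local axes


def _norm(v):
    return np.sqrt(np.einsum("...a,...a->...", v, v))


def _unit(v):
    return v / _norm(v)[..., None]


def _gather_frame_coords(coords, atomic: AtomicMultipoles):
    """Per-site copies of (own, frame-atom) positions: (n,3) and (n,3,3)."""
    fa = np.maximum(atomic.frame_atoms, 0)
    return coords[np.arange(atomic.n_sites)], coords[fa]


def _frames_from_gathered(r_self, r_f, atomic: AtomicMultipoles, check=True):
    """Rotation matrices (n,3,3) from gathered coordinates; complex safe."""
    n = atomic.n_sites
    dtype = r_self.dtype
    R = np.broadcast_to(np.eye(3, dtype=dtype), (n, 3, 3)).copy()
    styles = np.asarray(atomic.frame_style)

    def vecs(idx_sites, k):
        return r_f[idx_sites, k] - r_self[idx_sites]

    for style in ("zonly", "zthenx", "bisector", "zbisector"):
        sites = np.nonzero(styles == style)[0]
        if len(sites) == 0:
            continue
        u1 = vecs(sites, 0)
        if style == "zonly":
            ez = _unit(u1)
            # deterministic perpendicular: axis least aligned with ez
            seed = np.zeros_like(ez)
            pick = np.argmin(np.abs(ez.real), axis=1) if np.iscomplexobj(ez) \
                else np.argmin(np.abs(ez), axis=1)
            seed[np.arange(len(sites)), pick] = 1.0
            ex = seed - np.einsum("pa,pa->p", seed, ez)[:, None] * ez
        elif style == "zthenx":
            u2 = vecs(sites, 1)
            ez = _unit(u1)
            ex = u2 - np.einsum("pa,pa->p", u2, ez)[:, None] * ez
        elif style == "bisector":
            u2 = vecs(sites, 1)
            ez = _unit(u1) + _unit(u2)
            ez = _unit(ez)
            ex = u1 - np.einsum("pa,pa->p", u1, ez)[:, None] * ez
        else:  # zbisector
            u2 = vecs(sites, 1)
            u3 = vecs(sites, 2)
            ez = _unit(u1)
            bis = _unit(u2) + _unit(u3)
            ex = bis - np.einsum("pa,pa->p", bis, ez)[:, None] * ez
        nx = _norm(ex)
        if check and not np.iscomplexobj(nx):
            bad = nx < 1e-8
            if np.any(bad):
                raise DegenerateFrameError(
                    f"collinear frame atoms for sites {sites[bad].tolist()} "
                    f"(style {style})")
        ex = ex / nx[:, None]
        ey = np.cross(ez, ex)
        R[sites] = np.stack([ex, ey, ez], axis=-1)
    return R


def _frames(coords, atomic: AtomicMultipoles, check=True):
    r_self, r_f = _gather_frame_coords(coords, atomic)
    return _frames_from_gathered(r_self, r_f, atomic, check=check)


def rotate_multipoles_to_global(atomic: AtomicMultipoles,
                                coords_bohr) -> GlobalMultipoles:
    """Rotate local-frame dipoles/quadrupoles into the global frame.

    Charges are frame invariant; ``p_g = R p_l`` and ``Q_g = R Q_l R^T``.
    """
    R = _frames(np.asarray(coords_bohr), atomic)
    p = np.einsum("nab,nb->na", R, atomic.dipole_local)
    Q = np.einsum("nab,nbc,ndc->nad", R, atomic.quad_local, R)
    return GlobalMultipoles(atomic.charge.copy(), p, Q, R)


def frame_chain_rule(coords_bohr, atomic: AtomicMultipoles,
                     dE_dp, dE_dQ) -> np.ndarray:
    """Gradient contribution from the coordinate dependence of the local
    frames, via complex-step differentiation of the rotation map.

    ``dE_dp`` (n,3) and ``dE_dQ`` (n,3,3) are the accumulated derivatives of
    the total energy with respect to the *global* dipoles and quadrupoles.
    """
    n = atomic.n_sites
    grad = np.zeros((n, 3))
    h = _CSTEP
    fa = atomic.frame_atoms
    base = np.asarray(coords_bohr)

    active = np.array([s != "none" for s in atomic.frame_style])
    if not np.any(active):
        return grad

    r_self0, r_f0 = _gather_frame_coords(base, atomic)
    roles = [np.arange(n), fa[:, 0], fa[:, 1], fa[:, 2]]
    for role_k, role in enumerate(roles):
        valid = active & (role >= 0)
        if not np.any(valid):
            continue
        for comp in range(3):
            r_self = r_self0.astype(complex)
            r_f = r_f0.astype(complex)
            # each site owns its gathered copies, so sites sharing an atom
            # do not interfere
            if role_k == 0:
                r_self[valid, comp] += 1j * h
            else:
                r_f[valid, role_k - 1, comp] += 1j * h
            R = _frames_from_gathered(r_self, r_f, atomic, check=False)
            p = np.einsum("nab,nb->na", R, atomic.dipole_local)
            Q = np.einsum("nab,nbc,ndc->nad", R, atomic.quad_local, R)
            dE = (np.einsum("na,na->n", dE_dp, p.imag)
                  + np.einsum("nab,nab->n", dE_dQ, Q.imag)) / h
            np.add.at(grad, (role[valid], comp), dE[valid])
    return grad


# ---------------------------------------------------------------------------
# Pair masks
# ---------------------------------------------------------------------------

@dataclass
class PairMasks:
    """Per-pair scale factors derived from the bonded topology.

    ``perm``: permanent electrostatics (1-2/1-3 excluded, 1-4 and 1-5 scaled);
    ``field``: permanent-field mask for polarization (group based);
    ``vdw``: van der Waals (1-2/1-3 excluded);
    ``bond_dist``: graph distance clipped at 5.
    """

    perm: np.ndarray
    field: np.ndarray
    vdw: np.ndarray
    bond_dist: np.ndarray


def build_pair_masks(structure: Structure, atomic: Optional[AtomicMultipoles] = None,
                     perm_scales=(0.0, 0.0, 0.4, 0.8),
                     vdw_scales=(0.0, 0.0, 1.0)) -> PairMasks:
    """Build symmetric pair scale matrices from the bonded graph (AMOEBA
    conventions: permanent 1-2=0, 1-3=0, 1-4=0.4, 1-5=0.8; vdW 1-2=0, 1-3=0).

    The polarization field mask zeroes pairs inside the same polarization
    group (when ``atomic`` provides group ids)."""
    n = structure.n_atoms
    dist = np.full((n, n), 9, dtype=int)
    np.fill_diagonal(dist, 0)
    adj = structure.neighbors
    # BFS to depth 4
    for start in range(n):
        frontier = [start]
        seen = {start}
        for depth in range(1, 5):
            nxt = []
            for a in frontier:
                for b in adj[a]:
                    if b not in seen:
                        seen.add(b)
                        dist[start, b] = min(dist[start, b], depth)
                        nxt.append(b)
            frontier = nxt
    dist = np.minimum(dist, dist.T)

    perm = np.ones((n, n))
    vdw = np.ones((n, n))
    for d, sc in zip((1, 2, 3, 4), perm_scales):
        perm[dist == d] = sc
    for d, sc in zip((1, 2, 3), vdw_scales):
        vdw[dist == d] = sc
    np.fill_diagonal(perm, 0.0)
    np.fill_diagonal(vdw, 0.0)

    field = np.ones((n, n))
    if atomic is not None:
        same = atomic.group_id[:, None] == atomic.group_id[None, :]
        field[same] = 0.0
    np.fill_diagonal(field, 0.0)
    return PairMasks(perm, field, vdw, dist)


# ---------------------------------------------------------------------------
# Permanent electrostatics
# ---------------------------------------------------------------------------

@dataclass
class ElectrostaticsResult:
    energy: float
    grad: np.ndarray          # (n,3) at fixed global moments
    dE_dp: np.ndarray         # (n,3) wrt global dipoles
    dE_dQ: np.ndarray         # (n,3,3) wrt global quadrupoles
    potential: np.ndarray     # (n,) unmasked potential at each site (diagnostics)
    pair_energy: np.ndarray = None  # (npair,) masked per-pair energies


def _acc3(n, idx, w):
    """Scatter-add (npair,3) rows into an (n,3) array via bincount."""
    return np.stack([np.bincount(idx, weights=w[:, c], minlength=n)
                     for c in range(3)], axis=1)


def _acc33(n, idx, w):
    out = np.empty((n, 3, 3))
    for a in range(3):
        for b in range(3):
            out[:, a, b] = np.bincount(idx, weights=w[:, a, b], minlength=n)
    return out


def _pair_indices(n, pairs=None):
    if pairs is not None:
        return pairs
    iu, ju = np.triu_indices(n, k=1)
    return iu, ju


def permanent_electrostatics(gm: GlobalMultipoles, coords_bohr, masks: PairMasks,
                             pairs=None, grad=True) -> ElectrostaticsResult:
    """Masked pairwise multipole-multipole energy through quadrupole order.

    Coincident sites raise a singularity error (division blows up -> checked).
    """
    coords = np.asarray(coords_bohr)
    n = len(coords)
    iu, ju = _pair_indices(n, pairs)
    s = coords[ju] - coords[iu]
    r2 = np.einsum("pa,pa->p", s, s)
    if np.any(r2 < 1e-20):
        bad = int(np.argmin(r2))
        raise ZeroDivisionError(
            f"coincident sites {iu[bad]} and {ju[bad]} in electrostatics")
    scale = masks.perm[iu, ju]

    E, dE, dpi, dpj, dQi, dQj = pair_multipole_energy(
        s, gm.charge[iu], gm.charge[ju], gm.dipole[iu], gm.dipole[ju],
        gm.quad[iu], gm.quad[ju], grad=grad)
    energy = float(np.dot(E, scale))

    gradient = np.zeros((n, 3))
    dE_dp = np.zeros((n, 3))
    dE_dQ = np.zeros((n, 3, 3))
    if grad:
        w = scale[:, None]
        gradient = _acc3(n, ju, w * dE) - _acc3(n, iu, w * dE)
        dE_dp = _acc3(n, iu, w * dpi) + _acc3(n, ju, w * dpj)
        ws = scale[:, None, None]
        dE_dQ = _acc33(n, iu, ws * dQi) + _acc33(n, ju, ws * dQj)

    # unmasked per-site potential (monitoring / embedding diagnostics)
    r = np.sqrt(r2)
    ir = 1.0 / r
    ir3 = ir ** 3
    ir5 = ir3 * ir * ir
    pis = np.einsum("pa,pa->p", gm.dipole[iu], s)
    pjs = np.einsum("pa,pa->p", gm.dipole[ju], s)
    sQis = np.einsum("pa,pab,pb->p", s, gm.quad[iu], s)
    sQjs = np.einsum("pa,pab,pb->p", s, gm.quad[ju], s)
    pot = (np.bincount(ju, gm.charge[iu] * ir + pis * ir3 + sQis * ir5,
                       minlength=n)
           + np.bincount(iu, gm.charge[ju] * ir - pjs * ir3 + sQjs * ir5,
                         minlength=n))
    return ElectrostaticsResult(energy, gradient, dE_dp, dE_dQ, pot,
                                E * scale)


# ---------------------------------------------------------------------------
# Buffered 14-7 van der Waals
# ---------------------------------------------------------------------------

@dataclass
class VdwParams:
    """Per-atom buffered 14-7 parameters in atomic units, with hydrogen
    reduction factors and the heavy-atom partner index for reduced sites."""

    rmin: np.ndarray       # (n,) bohr (pair minimum for like pairs)
    eps: np.ndarray        # (n,) hartree
    reduction: np.ndarray  # (n,)
    heavy: np.ndarray      # (n,) int, -1 when not reduced


def compile_vdw(structure: Structure, params: ForceFieldParams) -> VdwParams:
    n = structure.n_atoms
    rmin = np.zeros(n)
    eps = np.zeros(n)
    red = np.ones(n)
    heavy = -np.ones(n, dtype=int)
    adj = structure.neighbors
    for i in range(n):
        tid = int(structure.type_ids[i])
        if tid not in params.vdw:
            raise ParameterLookupError("vdw", (tid,))
        r, e, f = params.vdw[tid]
        rmin[i] = r * units.BOHR_PER_ANGSTROM
        eps[i] = e * units.HARTREE_PER_KCALMOL
        if f != 1.0:
            if len(adj[i]) != 1:
                raise ParameterLookupError("vdw-reduction (needs univalent atom)",
                                           (tid,))
            red[i] = f
            heavy[i] = adj[i][0]
    return VdwParams(rmin, eps, red, heavy)


def buffered_14_7(coords_bohr, vdw: VdwParams, masks: PairMasks,
                  pairs=None, delta=0.07, gamma=0.12):
    """Buffered 14-7 energy and gradient with cubic-mean r_min and HHG epsilon
    combining rules; hydrogen reduction moves the interaction site toward the
    bonded heavy atom."""
    coords = np.asarray(coords_bohr)
    n = len(coords)
    # interaction sites
    x = coords.copy()
    redd = vdw.heavy >= 0
    x[redd] = (coords[vdw.heavy[redd]]
               + vdw.reduction[redd, None] * (coords[redd] - coords[vdw.heavy[redd]]))
    iu, ju = _pair_indices(n, pairs)
    scale = masks.vdw[iu, ju]
    act = (scale != 0.0) & (vdw.eps[iu] * vdw.eps[ju] > 0.0)
    iu, ju, scale = iu[act], ju[act], scale[act]
    s = x[ju] - x[iu]
    r = np.sqrt(np.einsum("pa,pa->p", s, s))
    if np.any(r < 1e-10):
        raise ZeroDivisionError("coincident van der Waals sites")
    ri, rj = vdw.rmin[iu], vdw.rmin[ju]
    rm = (ri ** 3 + rj ** 3) / (ri ** 2 + rj ** 2)
    ei, ej = vdw.eps[iu], vdw.eps[ju]
    em = 4.0 * ei * ej / (np.sqrt(ei) + np.sqrt(ej)) ** 2
    E, dE_dr = _b147_kernel(r, rm, em, delta, gamma)
    energy = float(np.dot(E, scale))
    g = (scale * dE_dr / r)[:, None] * s
    grad = _acc3(n, ju, g) - _acc3(n, iu, g)
    # redistribute forces from reduced sites
    if np.any(redd):
        gr = grad[redd] * (1.0 - vdw.reduction[redd, None])
        grad_full = grad.copy()
        grad_full[redd] = grad[redd] * vdw.reduction[redd, None]
        np.add.at(grad_full, vdw.heavy[redd], gr)
        grad = grad_full
    return energy, grad, (iu, ju, E * scale)


# ---------------------------------------------------------------------------
# Valence terms
# ---------------------------------------------------------------------------

@dataclass
class CompiledValence:
    """Unit-converted per-term parameter arrays for one term list."""

    bond_idx: np.ndarray
    bond_k: np.ndarray
    bond_r0: np.ndarray
    bond_cubic: float
    bond_quartic: float
    angle_idx: np.ndarray
    angle_k: np.ndarray
    angle_t0: np.ndarray
    angle_coeffs: tuple
    strbnd_idx: np.ndarray
    strbnd_k1: np.ndarray
    strbnd_k2: np.ndarray
    strbnd_r0ij: np.ndarray
    strbnd_r0kj: np.ndarray
    strbnd_t0: np.ndarray
    opbend_idx: np.ndarray
    opbend_k: np.ndarray
    torsion_idx: np.ndarray     # one row per Fourier term
    torsion_V: np.ndarray
    torsion_gamma: np.ndarray
    torsion_n: np.ndarray
    pitors_idx: np.ndarray
    pitors_k: np.ndarray
    tortors: list               # (idx_array(m,5), spline) tuples


def compile_valence_terms(structure: Structure, params: ForceFieldParams,
                          topo: ValenceTopology) -> CompiledValence:
    """Resolve parameters for every tuple of ``topo`` and convert to a.u.

    Missing bond/angle/torsion records raise ParameterLookupError naming the
    type tuple; strbnd/opbend/pitors/tortors tuples without records are
    treated as absent terms.
    """
    tids = structure.type_ids
    kc = units.HARTREE_PER_KCALMOL
    A = units.ANGSTROM_PER_BOHR  # 1 bohr in Angstrom

    b_idx, b_k, b_r0 = [], [], []
    for (i, j) in topo.bonds:
        key = _canon_pair(int(tids[i]), int(tids[j]))
        if key not in params.bonds:
            raise ParameterLookupError("bond", key)
        k, r0 = params.bonds[key]
        b_idx.append((i, j))
        b_k.append(k * kc * A ** 2)            # kcal/A^2 -> Eh/bohr^2
        b_r0.append(r0 * units.BOHR_PER_ANGSTROM)

    a_idx, a_k, a_t0 = [], [], []
    for (i, j, k_) in topo.angles:
        key = _canon_triple(int(tids[i]), int(tids[j]), int(tids[k_]))
        if key not in params.angles:
            raise ParameterLookupError("angle", key)
        kf, t0 = params.angles[key]
        a_idx.append((i, j, k_))
        a_k.append(kf * kc)                    # kcal/rad^2 -> Eh/rad^2
        a_t0.append(t0 * units.RAD_PER_DEG)

    s_idx, s_k1, s_k2, s_rij, s_rkj, s_t0 = [], [], [], [], [], []
    for (i, j, k_) in topo.strbnd:
        key = _canon_triple(int(tids[i]), int(tids[j]), int(tids[k_]))
        if key not in params.strbnd:
            continue
        k1, k2 = params.strbnd[key]
        if key != (int(tids[i]), int(tids[j]), int(tids[k_])):
            k1, k2 = k2, k1
        bij = _canon_pair(int(tids[i]), int(tids[j]))
        bkj = _canon_pair(int(tids[k_]), int(tids[j]))
        akey = _canon_triple(int(tids[i]), int(tids[j]), int(tids[k_]))
        if bij not in params.bonds or bkj not in params.bonds \
                or akey not in params.angles:
            raise ParameterLookupError("strbnd reference", key)
        s_idx.append((i, j, k_))
        s_k1.append(k1 * kc * A)               # kcal/(A rad) -> Eh/(bohr rad)
        s_k2.append(k2 * kc * A)
        s_rij.append(params.bonds[bij][1] * units.BOHR_PER_ANGSTROM)
        s_rkj.append(params.bonds[bkj][1] * units.BOHR_PER_ANGSTROM)
        s_t0.append(params.angles[akey][1] * units.RAD_PER_DEG)

    o_idx, o_k = [], []
    for tup in topo.opbend:
        key = _lookup_opbend_key(tids, tup, params)
        if key is None:
            continue
        o_idx.append(tup)
        o_k.append(params.opbend[key] * kc)

    t_idx, t_V, t_g, t_n = [], [], [], []
    for tup in topo.torsions:
        key = tuple(int(tids[x]) for x in tup)
        terms = params.torsions.get(_canon_quad(key))
        if terms is None:
            raise ParameterLookupError("torsion", key)
        for (V, gamma, n_) in terms:
            t_idx.append(tup)
            t_V.append(V * kc)
            t_g.append(gamma * units.RAD_PER_DEG)
            t_n.append(n_)

    p_idx, p_k = [], []
    for tup in topo.pitors:
        key = _canon_pair(int(tids[tup[0]]), int(tids[tup[1]]))
        if key not in params.pitors:
            continue
        p_idx.append(tup)
        p_k.append(params.pitors[key] * kc)

    tt_groups = {}
    for tup in topo.tortors:
        key = _lookup_tortor_key(tids, tup, params)
        if key is None:
            continue
        path = tup if key == tuple(int(tids[x]) for x in tup) else tup[::-1]
        tt_groups.setdefault(key, []).append(path)
    tortors = []
    for key, paths in sorted(tt_groups.items()):
        ang1, ang2, grid = params.tortors[key]
        spl = _periodic_bicubic(ang1, ang2, grid * kc)
        tortors.append((np.array(paths, dtype=int), spl))

    def arr(x, dt=float):
        return np.array(x, dtype=dt) if x else np.zeros((0,), dtype=dt)

    def idx(x, w):
        return np.array(x, dtype=int) if x else np.zeros((0, w), dtype=int)

    ac = params.angle_coeffs
    return CompiledValence(
        idx(b_idx, 2), arr(b_k), arr(b_r0),
        params.bond_cubic * A, params.bond_quartic * A ** 2,
        idx(a_idx, 3), arr(a_k), arr(a_t0), ac,
        idx(s_idx, 3), arr(s_k1), arr(s_k2), arr(s_rij), arr(s_rkj), arr(s_t0),
        idx(o_idx, 4), arr(o_k),
        idx(t_idx, 4), arr(t_V), arr(t_g), arr(t_n, int),
        idx(p_idx, 6), arr(p_k),
        tortors,
    )


def _periodic_bicubic(ang1, ang2, grid, pad=3):
    """Bicubic spline of a torsion-torsion map, periodically padded so the
    value and slope are consistent across the +-180 degree seam.

    Grids spanning the full period (first/last rows and columns matching) are
    padded by ``pad`` knots of periodic images on every side; other grids are
    splined as-is with clamped edges.
    """

    def full_period(a, g_first, g_last):
        return (abs((a[-1] - a[0]) - 360.0) < 1e-9
                and np.allclose(g_first, g_last))

    a1, a2, g = np.asarray(ang1, float), np.asarray(ang2, float), np.asarray(grid)
    if full_period(a1, g[0], g[-1]):
        a1 = np.concatenate([a1[-1 - pad:-1] - 360.0, a1, a1[1:1 + pad] + 360.0])
        g = np.vstack([g[-1 - pad:-1], g, g[1:1 + pad]])
    if full_period(a2, g[:, 0], g[:, -1]):
        a2 = np.concatenate([a2[-1 - pad:-1] - 360.0, a2, a2[1:1 + pad] + 360.0])
        g = np.hstack([g[:, -1 - pad:-1], g, g[:, 1:1 + pad]])
    return RectBivariateSpline(a1, a2, g, kx=3, ky=3)


def _cross(a, b):
    """Cross product along the last axis (faster than np.cross for (m,3))."""
    c = np.empty(np.broadcast(a, b).shape, dtype=np.result_type(a, b))
    c[..., 0] = a[..., 1] * b[..., 2] - a[..., 2] * b[..., 1]
    c[..., 1] = a[..., 2] * b[..., 0] - a[..., 0] * b[..., 2]
    c[..., 2] = a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]
    return c


def _cnorm(v):
    return np.sqrt(np.einsum("...a,...a->...", v, v))


def _bond_E(X, cv):
    d = _cnorm(X[:, 1] - X[:, 0]) - cv.bond_r0
    return cv.bond_k * d * d * (1.0 + cv.bond_cubic * d + cv.bond_quartic * d * d)


def _angle_value(X):
    u = X[:, 0] - X[:, 1]
    v = X[:, 2] - X[:, 1]
    cos = np.einsum("pa,pa->p", u, v) / (_cnorm(u) * _cnorm(v))
    return np.arccos(cos)


def _angle_poly(d, k, coeffs):
    c3, c4, c5, c6 = coeffs
    return k * d * d * (1.0 + c3 * d + c4 * d ** 2 + c5 * d ** 3 + c6 * d ** 4)


def _angle_E(X, cv):
    return _angle_poly(_angle_value(X) - cv.angle_t0, cv.angle_k, cv.angle_coeffs)


def _strbnd_E(X, cv):
    d1 = _cnorm(X[:, 0] - X[:, 1]) - cv.strbnd_r0ij
    d2 = _cnorm(X[:, 2] - X[:, 1]) - cv.strbnd_r0kj
    dt = _angle_value(X) - cv.strbnd_t0
    return (cv.strbnd_k1 * d1 + cv.strbnd_k2 * d2) * dt


def _opbend_E(X, cv):
    # X rows: (out_atom a, centre d, b, c); chi = angle of bond d-a out of the
    # b-d-c plane (Wilson-Decius-Cross).
    a, d, b, c = X[:, 0], X[:, 1], X[:, 2], X[:, 3]
    nvec = _cross(b - d, c - d)
    u = a - d
    sin_chi = np.einsum("pa,pa->p", nvec, u) / (_cnorm(nvec) * _cnorm(u))
    chi = np.arcsin(sin_chi)
    return _angle_poly(chi, cv.opbend_k, cv.angle_coeffs)


def _torsion_cos_sin(X):
    b1 = X[:, 1] - X[:, 0]
    b2 = X[:, 2] - X[:, 1]
    b3 = X[:, 3] - X[:, 2]
    n1 = _cross(b1, b2)
    n2 = _cross(b2, b3)
    nn = _cnorm(n1) * _cnorm(n2)
    cos = np.einsum("pa,pa->p", n1, n2) / nn
    sin = np.einsum("pa,pa->p", _cross(n1, n2), b2) / (nn * _cnorm(b2))
    return cos, sin


def _torsion_E(X, cv):
    cos, sin = _torsion_cos_sin(X)
    # cos(n phi), sin(n phi) by recurrence; holomorphic in the coordinates
    cn, sn = cos.copy(), sin.copy()
    E = np.zeros_like(cos)
    nmax = int(cv.torsion_n.max()) if len(cv.torsion_n) else 0
    cos_n = {1: (cn, sn)}
    for m in range(2, nmax + 1):
        cm = cos_n[m - 1][0] * cos - cos_n[m - 1][1] * sin
        sm = cos_n[m - 1][1] * cos + cos_n[m - 1][0] * sin
        cos_n[m] = (cm, sm)
    for m in range(1, nmax + 1):
        sel = cv.torsion_n == m
        if not np.any(sel):
            continue
        cm, sm = cos_n[m]
        E = E + np.where(
            sel,
            0.5 * cv.torsion_V * (1.0 + cm * np.cos(cv.torsion_gamma)
                                  + sm * np.sin(cv.torsion_gamma)),
            0.0)
    return E


def _pitors_E(X, cv):
    # X rows: (a, b, c1, d1, e1, f1); 2-fold torsion about the a-b bond of the
    # two substituent-plane normals: E = k sin^2(phi), zero when coplanar.
    a, b = X[:, 0], X[:, 1]
    na = _cross(X[:, 2] - a, X[:, 3] - a)
    nb = _cross(X[:, 4] - b, X[:, 5] - b)
    axis = b - a
    # project the normals perpendicular to the axis, measure the twist
    ua = _cross(na, axis)
    ub = _cross(nb, axis)
    cos = np.einsum("pa,pa->p", ua, ub) / (_cnorm(ua) * _cnorm(ub))
    return cv.pitors_k * (1.0 - cos * cos)


_VALENCE_EVALS = (
    ("bond", "bond_idx", _bond_E),
    ("angle", "angle_idx", _angle_E),
    ("strbnd", "strbnd_idx", _strbnd_E),
    ("opbend", "opbend_idx", _opbend_E),
    ("torsion", "torsion_idx", _torsion_E),
    ("pitors", "pitors_idx", _pitors_E),
)


def valence_energy(coords_bohr, cv: CompiledValence, grad=True):
    """Total valence energy, gradient and per-class decomposition (a.u.)."""
    coords = np.asarray(coords_bohr, dtype=float)
    n = len(coords)
    total = 0.0
    gradient = np.zeros((n, 3)) if grad else None
    decomp = {}
    h = _CSTEP

    for name, idx_attr, fn in _VALENCE_EVALS:
        idx = getattr(cv, idx_attr)
        if len(idx) == 0:
            decomp[name] = 0.0
            continue
        X = coords[idx]  # (m, k, 3)
        E = fn(X, cv)
        decomp[name] = float(E.sum())
        total += decomp[name]
        if grad:
            k = X.shape[1]
            for slot in range(k):
                for comp in range(3):
                    Xc = X.astype(complex)
                    Xc[:, slot, comp] += 1j * h
                    dE = fn(Xc, cv).imag / h
                    np.add.at(gradient, (idx[:, slot], comp), dE)

    # torsion-torsion: spline partials x complex-step angle derivatives
    e_tt = 0.0
    for idx, spl in cv.tortors:
        X = coords[idx]
        phi = _dihedral_deg(X[:, :4])
        psi = _dihedral_deg(X[:, 1:])
        e = spl.ev(phi, psi)
        e_tt += float(e.sum())
        if grad:
            dphi = spl.ev(phi, psi, dx=1)
            dpsi = spl.ev(phi, psi, dy=1)
            for slot in range(5):
                for comp in range(3):
                    Xc = X.astype(complex)
                    Xc[:, slot, comp] += 1j * h
                    dphi_dx = _dihedral_deriv_deg(Xc[:, :4], h)
                    dpsi_dx = _dihedral_deriv_deg(Xc[:, 1:], h)
                    np.add.at(gradient, (idx[:, slot], comp),
                              dphi * dphi_dx + dpsi * dpsi_dx)
    decomp["tortors"] = e_tt
    total += e_tt
    return total, gradient, decomp


def _dihedral_deg(X):
    cos, sin = _torsion_cos_sin(X)
    return np.degrees(np.arctan2(sin, cos))


def _dihedral_deriv_deg(Xc, h):
    """d(phi_deg)/dx for complex-perturbed coordinates: the angle derivative is
    cos*d(sin) - sin*d(cos) for the normalized (cos, sin) pair."""
    cos, sin = _torsion_cos_sin(Xc)
    d = (cos.real * sin.imag - sin.real * cos.imag) / h
    return np.degrees(d)
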