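"""Mutual-polarization QM/MM coupling.

Implements the variational embedding energy

    E(P, mu) = E_qm[P] + E_ele[P] + E_pol[P, mu] + E_mm[mu]

with one self-consistent loop over the electronic degrees of freedom P (held
by a backend) and the classical induced dipoles mu.  The environment enters
the backend through a descriptor of point multipoles (boundary-adjusted: MM1
sites zeroed, MM2 augmented, PB atoms never classical sources) plus the
current induced dipoles; the backend returns its density, energies and fields.

The package ships a *classical surrogate backend* whose "density" is its own
set of induced dipoles on the QM atoms: every energy, field and gradient is
then classical, and the joint QM+MM polarization problem has an exact dense
oracle, which makes the whole machinery verifiable to machine precision.  A
real electronic-structure adapter can register through the same contract.
"""

from __future__ import annotations

import json
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.linalg

from . import ffio, mm_energy, polarization
from ._kernels import (
    pair_dipole_dipole_grad,
    pair_field,
    pair_mu_dot_field_grad,
    thole_factors,
)
from .errors import ConvergenceError, PolQmmmError, ValidationError

__all__ = [
    "EcpSpec",
    "QmBackend",
    "SurrogateBackend",
    "surrogate_backend",
    "EnvironmentDescriptor",
    "assemble_environment_operators",
    "QmmmSystem",
    "ScfState",
    "scf_mutual_polarization",
    "total_gradient",
    "register_backend",
    "get_backend",
]

DEFAULT_SCF_TOL = 1e-8
MAX_MACRO_CYCLES = 200


# ---------------------------------------------------------------------------
# Pseudobond ECP specification
# ---------------------------------------------------------------------------

@dataclass
class EcpSpec:
    """One-Gaussian effective core potential for a pseudobond atom type,
    V(r) = a * exp(-b r^2) acting on the valence electrons, plus a minimal
    STO-2G-style basis with shared s/p exponents (4 parameters).

    The parameters are empirical per pseudobond type (Cps-C, Cps-N, Cps-C=O)
    and must be supplied by the user for a real electronic-structure backend;
    the classical surrogate backend ignores them.
    """

    pb_type: str
    a: float = 0.0
    b: float = 1.0
    n_valence_electrons: int = 7
    basis: tuple = (0.0, 0.0, 0.0, 0.0)  # (exp1, exp2, coef_s, coef_p)

    def __post_init__(self):
        if self.b <= 0:
            raise ValidationError("ECP exponent b must be positive")
        if len(self.basis) != 4:
            raise ValidationError("pseudobond basis needs exactly 4 parameters")

    @classmethod
    def load(cls, path):
        """Load a {pb_type: {a, b, basis}} table from JSON."""
        with open(path) as fh:
            table = json.load(fh)
        return {k: cls(pb_type=k, **v) for k, v in table.items()}


# ---------------------------------------------------------------------------
# Backend contract
# ---------------------------------------------------------------------------

class QmBackend(ABC):
    """Contract between the embedding driver and an electronic-structure code.

    The driver talks to the backend in terms of *site models*: the backend
    exposes, for each QM atom, an effective charge and (optionally) an
    isotropic polarizability, and contributes its internal energy terms.  For
    a classical surrogate these are the whole story; a real SCF adapter would
    additionally consume the environment descriptor for its one-electron
    Hamiltonian and return density-derived fields.
    """

    name = "abstract"
    capabilities = frozenset()

    @abstractmethod
    def site_model(self, n_qm):
        """Return (charges, alphas, tholes) arrays over the QM atoms (a.u.)."""

    def internal_valence(self) -> bool:
        """Whether the classical valence terms of the QM subsystem should be
        retained (True for the surrogate, False for a real QM backend)."""
        return False


_BACKENDS = {}


def register_backend(name, factory):
    _BACKENDS[name] = factory


def get_backend(name, **kwargs) -> QmBackend:
    if name not in _BACKENDS:
        raise PolQmmmError(
            f"backend '{name}' is not registered (available: "
            f"{sorted(_BACKENDS)}); a real electronic-structure backend is an "
            f"optional extra")
    return _BACKENDS[name](**kwargs)


class SurrogateBackend(QmBackend):
    """Classical stand-in electronic structure: fixed point charges plus
    isotropic induced dipoles on the QM atoms.

    Its "density" is the induced-dipole set, so mutual polarization with the
    MM environment is an exactly solvable joint linear problem.  The classical
    valence terms of the QM subsystem are retained as its internal bonded
    energy so that QM fragments stay bound during dynamics.
    """

    name = "surrogate"
    capabilities = frozenset({"scf", "gradient", "transition_fields"})

    def __init__(self, charges, alphas=None, thole=0.39):
        self.charges = np.atleast_1d(np.asarray(charges, dtype=float))
        if alphas is None:
            alphas = np.zeros_like(self.charges)
        self.alphas = np.atleast_1d(np.asarray(alphas, dtype=float))
        if np.any(self.alphas < 0):
            raise ValidationError("surrogate polarizabilities must be >= 0")
        self.thole = thole

    def site_model(self, n_qm):
        if len(self.charges) != n_qm:
            raise ValidationError(
                f"surrogate backend has {len(self.charges)} charges for "
                f"{n_qm} QM atoms")
        return self.charges, self.alphas, np.full(n_qm, self.thole)

    def internal_valence(self):
        return True


def surrogate_backend(qm_atoms, charges, alphas=None, thole=0.39):
    """Build a classical surrogate backend for the given QM atom list."""
    del qm_atoms  # the system binds atoms to the backend; kept for the API
    return SurrogateBackend(charges, alphas, thole)


def surrogate_from_force_field(structure, params, qm_atoms, polarizable=True,
                               thole=0.39):
    """Surrogate backend whose charges/polarizabilities are the classical
    monopoles and alphas of the QM atoms (the natural classical stand-in)."""
    from . import units as _u

    charges, alphas = [], []
    for a in sorted(qm_atoms):
        tid = int(structure.type_ids[a])
        rec = params.multipoles.get(tid)
        charges.append(rec.charge if rec else 0.0)
        pol = params.polarize.get(tid)
        alphas.append(pol[0] * _u.BOHR_PER_ANGSTROM ** 3
                      if (pol and polarizable) else 0.0)
    return SurrogateBackend(np.array(charges), np.array(alphas), thole)


register_backend("surrogate",
                 lambda **kw: SurrogateBackend(**kw))


# ---------------------------------------------------------------------------
# Environment descriptor
# ---------------------------------------------------------------------------

@dataclass
class EnvironmentDescriptor:
    """Classical sources as a backend consumes them: positions (bohr), point
    charges, global-frame dipoles and quadrupoles, and the current induced
    dipoles, all restricted to classical (non-QM, non-PB) sites."""

    site_ids: np.ndarray
    positions: np.ndarray
    charges: np.ndarray
    dipoles: np.ndarray
    quadrupoles: np.ndarray
    induced: np.ndarray


def assemble_environment_operators(gm: mm_energy.GlobalMultipoles, coords_bohr,
                                   mu_by_site, boundary_map: ffio.BoundaryMap
                                   ) -> EnvironmentDescriptor:
    """Collect the classical sources seen by the QM Hamiltonian.

    PB atoms must not appear among classical sources (their electrostatics
    lives in the QM subsystem); a nonzero classical multipole on a PB atom is
    a consistency error.
    """
    n = len(gm.charge)
    qm = boundary_map.qm_atoms
    for p in boundary_map.pb_atoms:
        if (abs(gm.charge[p]) > 0 or np.any(gm.dipole[p] != 0)
                or np.any(gm.quad[p] != 0)):
            raise ValidationError(
                f"PB atom {p} carries classical multipoles; boundary "
                f"adjustment must run before assembling environment operators")
    ids = np.array([i for i in range(n) if i not in qm], dtype=int)
    coords = np.asarray(coords_bohr)
    mu = np.zeros((len(ids), 3))
    if mu_by_site is not None:
        mu = np.asarray(mu_by_site)[ids]
    return EnvironmentDescriptor(ids, coords[ids], gm.charge[ids],
                                 gm.dipole[ids], gm.quad[ids], mu)


# ---------------------------------------------------------------------------
# SCF state
# ---------------------------------------------------------------------------

@dataclass
class ScfState:
    """Converged mutual-polarization solution with energy decomposition."""

    density: np.ndarray            # backend density handle (surrogate: mu_qm)
    mu: np.ndarray                 # (n, 3) induced dipoles on all atoms
    e_qm_internal: float
    e_ele_env: float
    e_pol_env: float
    e_mm: float
    e_total: float
    cycles: int
    converged: bool
    trace: list = field(default_factory=list)   # per-cycle functional values
    decomposition: dict = field(default_factory=dict)
    coords: Optional[np.ndarray] = None
    _cache: dict = field(default_factory=dict, repr=False)


# ---------------------------------------------------------------------------
# The coupled system
# ---------------------------------------------------------------------------

class QmmmSystem:
    """A partitioned structure + force field + backend, ready for energy,
    force and dynamics evaluations.

    With ``backend=None`` (and an empty partition) this is a pure AMOEBA-style
    classical system; with a backend, the QM atoms' classical multipoles are
    replaced by the backend's site model and the boundary adjustment of the
    pseudobond scheme is applied.
    """

    def __init__(self, structure: ffio.Structure, params: ffio.ForceFieldParams,
                 spec: Optional[ffio.PartitionSpec] = None,
                 backend: Optional[QmBackend] = None,
                 scf_tol: float = DEFAULT_SCF_TOL):
        self.structure = structure
        self.params = params
        self.spec = spec or ffio.PartitionSpec(set(), set(), "none")
        self.backend = backend
        self.scf_tol = scf_tol

        self.boundary = ffio.build_partition(structure, self.spec)
        self.atomic = ffio.assign_atomic_multipoles(structure, params)
        if self.spec.scheme == "pseudobond" and self.boundary.pb_atoms:
            self.adjusted = ffio.zero_and_redistribute(self.atomic, self.boundary)
        else:
            self.adjusted = self.atomic.copy()

        n = structure.n_atoms
        self.qm_atoms = sorted(self.boundary.qm_atoms)
        self.is_qm = np.zeros(n, dtype=bool)
        self.is_qm[self.qm_atoms] = True

        # electrostatic site model: classical everywhere, backend on QM atoms
        self.electro = self.adjusted.copy()
        if backend is not None and self.qm_atoms:
            q, a, t = backend.site_model(len(self.qm_atoms))
            for k, atom in enumerate(self.qm_atoms):
                self.electro.charge[atom] = q[k]
                self.electro.dipole_local[atom] = 0.0
                self.electro.quad_local[atom] = 0.0
                self.electro.alpha[atom] = a[k]
                self.electro.thole[atom] = t[k]
                self.electro.frame_style[atom] = "none"
                self.electro.frame_atoms[atom] = -1
        elif backend is None and self.qm_atoms:
            raise ValidationError("a non-empty QM partition needs a backend")

        self.masks = mm_energy.build_pair_masks(structure, self.atomic)
        self.vdw = mm_energy.compile_vdw(structure, params)
        # intra-QM dispersion/repulsion belongs to the backend
        self.vdw_masks = mm_energy.PairMasks(
            self.masks.perm, self.masks.field,
            self.masks.vdw * ~(self.is_qm[:, None] & self.is_qm[None, :]),
            self.masks.bond_dist)

        hybrid, mm_topo, qm_topo = ffio.enumerate_boundary_valence_terms(
            structure, self.boundary, params)
        classical = ffio.ValenceTopology(
            *[sorted(getattr(mm_topo, f) + getattr(hybrid, f))
              for f in ("bonds", "angles", "strbnd", "opbend",
                        "torsions", "pitors", "tortors")])
        self.hybrid_topology = hybrid
        self.valence_classical = mm_energy.compile_valence_terms(
            structure, params, classical)
        self.valence_qm = None
        if backend is not None and backend.internal_valence():
            self.valence_qm = mm_energy.compile_valence_terms(
                structure, params, qm_topo)

        # pair bookkeeping
        iu, ju = np.triu_indices(n, k=1)
        self.pairs = (iu, ju)
        zone = self.is_qm[iu].astype(int) + self.is_qm[ju].astype(int)
        self.pair_zone = zone  # 0 = MM-MM, 1 = QM-MM, 2 = QM-QM
        self.masses_amu = np.array(
            [params.atoms[int(t)][1] for t in structure.type_ids])

    # -- polarization helpers ---------------------------------------------

    def _field_pairs(self, coords):
        """Ordered (source, target) arrays for the permanent-field sum
        (topology-static, cached)."""
        if not hasattr(self, "_field_pairs_cache"):
            alpha = self.electro.alpha
            pol = np.nonzero(alpha > 0)[0]
            n = self.structure.n_atoms
            src = np.repeat(np.arange(n), len(pol))
            tgt = np.tile(pol, n)
            keep = src != tgt
            src, tgt = src[keep], tgt[keep]
            w = self.masks.field[src, tgt]
            act = w != 0
            self._field_pairs_cache = (pol, src[act], tgt[act], w[act])
        return self._field_pairs_cache

    def _static_field(self, gm, coords, pol, src, tgt, w):
        """Permanent field at polarizable sites; also returns the reusable
        pair geometry/damping for the gradient pass."""
        alpha, thole = self.electro.alpha, self.electro.thole
        F = np.zeros((len(pol), 3))
        geom = None
        if len(src):
            s = coords[tgt] - coords[src]
            r = np.sqrt(np.einsum("pa,pa->p", s, s))
            lams = thole_factors(r, alpha[src], alpha[tgt],
                                 thole[src], thole[tgt])
            f = pair_field(s, gm.charge[src], gm.dipole[src], gm.quad[src],
                           lams[0], lams[1], lams[2])
            np.add.at(F, np.searchsorted(pol, tgt), w[:, None] * f)
            geom = (s, lams)
        return F, geom

    # -- main entry points --------------------------------------------------

    def energy_and_forces(self, coords_bohr, guess=None, tol=None,
                          want_forces=True):
        """Single-point mutual-polarization energy (and forces).

        Returns ``(ScfState, forces)``; forces are ``None`` when
        ``want_forces`` is False.
        """
        coords = np.asarray(coords_bohr, dtype=float).reshape(-1, 3)
        tol = self.scf_tol if tol is None else tol
        state = scf_mutual_polarization(self, coords, guess=guess, tol=tol,
                                        want_forces=want_forces)
        return state, state._cache.get("forces")

    def minimize(self, coords_bohr, gtol=1e-5, maxiter=500):
        """Relax the geometry with L-BFGS on the mutual-polarization surface
        (used to prepare equilibrated starting points for NVE runs).

        Returns (relaxed coordinates (bohr), final energy).
        """
        from scipy.optimize import minimize as _minimize

        shape = np.asarray(coords_bohr, dtype=float).reshape(-1, 3).shape
        guess_holder = {"mu": None}

        def fun(x):
            state, forces = self.energy_and_forces(
                x.reshape(shape), guess=guess_holder["mu"])
            guess_holder["mu"] = state.mu
            return state.e_total, -forces.reshape(-1)

        out = _minimize(fun, np.asarray(coords_bohr, float).reshape(-1),
                        jac=True, method="L-BFGS-B",
                        options={"gtol": gtol, "maxiter": maxiter})
        return out.x.reshape(shape), float(out.fun)


# ---------------------------------------------------------------------------
# SCF over P (backend density) and mu (classical dipoles)
# ---------------------------------------------------------------------------

def scf_mutual_polarization(system: QmmmSystem, coords_bohr, guess=None,
                            tol: float = DEFAULT_SCF_TOL,
                            max_cycles: int = MAX_MACRO_CYCLES,
                            want_forces: bool = False) -> ScfState:
    """Alternate backend-density and induced-dipole updates to the joint
    variational minimum.

    For the surrogate backend both blocks are damped linear problems, solved
    exactly per block (block Gauss-Seidel), so the functional decreases
    monotonically and the converged energy equals the joint dense solve.
    ``guess`` may carry the previous induced dipoles over all atoms (n,3).
    """
    coords = np.asarray(coords_bohr, dtype=float).reshape(-1, 3)
    el = system.electro
    gm = mm_energy.rotate_multipoles_to_global(el, coords)

    pol, src, tgt, w = system._field_pairs(coords)
    E_static, field_geom = system._static_field(gm, coords, pol, src, tgt, w)

    n = system.structure.n_atoms
    trace = []
    qm_pol_mask = system.is_qm[pol]
    cycles = 0
    converged = True
    mu_flat = np.zeros(3 * len(pol))

    if len(pol):
        op = polarization.build_thole_interaction(
            coords, el.alpha, el.thole, site_index=pol)
        A = op.matrix
        E = E_static.reshape(-1)
        if guess is not None:
            mu_flat = np.asarray(guess, dtype=float)[pol].reshape(-1).copy()

        qm_idx = np.nonzero(np.repeat(qm_pol_mask, 3))[0]
        mm_idx = np.nonzero(np.repeat(~qm_pol_mask, 3))[0]
        if len(qm_idx) == 0 or len(mm_idx) == 0:
            # single classical block: one macro-cycle direct solve
            mu_flat = scipy.linalg.solve(A, E, assume_a="sym")
            cycles = 1
            trace.append(float(0.5 * mu_flat @ (A @ mu_flat) - mu_flat @ E))
        else:
            A_qq = A[np.ix_(qm_idx, qm_idx)]
            A_qm = A[np.ix_(qm_idx, mm_idx)]
            A_mm = A[np.ix_(mm_idx, mm_idx)]
            cq = scipy.linalg.cho_factor(A_qq)
            cm = scipy.linalg.cho_factor(A_mm)
            converged = False
            for cycle in range(1, max_cycles + 1):
                prev = mu_flat.copy()
                # backend block ("SCF step" of the surrogate density)
                mu_flat[qm_idx] = scipy.linalg.cho_solve(
                    cq, E[qm_idx] - A_qm @ mu_flat[mm_idx])
                # classical dipole block
                mu_flat[mm_idx] = scipy.linalg.cho_solve(
                    cm, E[mm_idx] - A_qm.T @ mu_flat[qm_idx])
                trace.append(float(0.5 * mu_flat @ (A @ mu_flat) - mu_flat @ E))
                change = float(np.sqrt(np.mean(
                    np.sum((mu_flat - prev).reshape(-1, 3) ** 2, axis=1))))
                cycles = cycle
                if change <= tol:
                    converged = True
                    break
            if not converged:
                raise ConvergenceError(
                    f"mutual polarization did not converge in {max_cycles} "
                    f"macro-cycles", trace)
        e_pol = float(0.5 * mu_flat @ (A @ mu_flat) - mu_flat @ E)
    else:
        cycles = 1
        e_pol = 0.0

    mu_sites = np.zeros((n, 3))
    if len(pol):
        mu_sites[pol] = mu_flat.reshape(-1, 3)

    # permanent electrostatics: one masked pass; zone split from pair energies
    iu, ju = system.pairs
    zone = system.pair_zone
    res = mm_energy.permanent_electrostatics(
        gm, coords, system.masks, pairs=system.pairs, grad=want_forces)
    perm_by_zone = {z: float(res.pair_energy[zone == z].sum()) for z in (0, 1, 2)}

    e_vdw_tot, g_vdw, (viu, vju, v_pair) = mm_energy.buffered_14_7(
        coords, system.vdw, system.vdw_masks, pairs=system.pairs)
    vzone = system.is_qm[viu].astype(int) + system.is_qm[vju].astype(int)
    e_vdw_mm = float(v_pair[vzone == 0].sum())
    e_vdw_env = float(v_pair[vzone == 1].sum())

    e_val_cl, g_val, dec_cl = mm_energy.valence_energy(
        coords, system.valence_classical, grad=want_forces)
    e_val_qm, g_val_qm = 0.0, None
    if system.valence_qm is not None:
        e_val_qm, g_val_qm, _ = mm_energy.valence_energy(
            coords, system.valence_qm, grad=want_forces)

    e_qm_internal = e_val_qm + perm_by_zone[2]
    e_ele_env = perm_by_zone[1] + e_vdw_env
    e_mm = e_val_cl + perm_by_zone[0] + e_vdw_mm
    e_total = e_qm_internal + e_ele_env + e_pol + e_mm

    density = mu_sites[system.qm_atoms] if system.qm_atoms else np.zeros((0, 3))
    state = ScfState(
        density=density, mu=mu_sites,
        e_qm_internal=e_qm_internal, e_ele_env=e_ele_env,
        e_pol_env=e_pol, e_mm=e_mm, e_total=e_total,
        cycles=cycles, converged=converged, trace=trace,
        decomposition={
            "valence_mm": e_val_cl, "valence_qm": e_val_qm,
            "mpole_mm": perm_by_zone[0], "mpole_env": perm_by_zone[1],
            "mpole_qm": perm_by_zone[2], "vdw_mm": e_vdw_mm,
            "vdw_env": e_vdw_env, "polarization": e_pol, **dec_cl},
        coords=coords.copy())
    state._cache = {"gm": gm, "pol": pol, "src": src, "tgt": tgt, "w": w,
                    "E_static": E_static}

    if want_forces:
        grad = res.grad + g_vdw + g_val
        if g_val_qm is not None:
            grad = grad + g_val_qm
        grad += _polarization_gradient(system, coords, gm, mu_sites, pol,
                                       src, tgt, w, res.dE_dp, res.dE_dQ,
                                       field_geom)
        state._cache["forces"] = -grad
    return state


def _polarization_gradient(system, coords, gm, mu, pol, src, tgt, w,
                           dE_dp, dE_dQ, field_geom=None):
    """Explicit coordinate derivatives of E_pol plus the frame chain rule for
    all electrostatic moment derivatives (permanent + polarization)."""
    el = system.electro
    alpha, thole = el.alpha, el.thole
    n = len(coords)
    grad = np.zeros((n, 3))
    dE_dp = dE_dp.copy()
    dE_dQ = dE_dQ.copy()
    if len(pol):
        # -mu . E_static term
        if len(src):
            if field_geom is not None:
                s, (lam3, lam5, lam7, lam9) = field_geom
            else:
                s = coords[tgt] - coords[src]
                r = np.sqrt(np.einsum("pa,pa->p", s, s))
                lam3, lam5, lam7, lam9 = thole_factors(
                    r, alpha[src], alpha[tgt], thole[src], thole[tgt])
            d_ds, d_dq, d_dp, d_dQ = pair_mu_dot_field_grad(
                s, gm.charge[src], gm.dipole[src], gm.quad[src], mu[tgt],
                lam3, lam5, lam7, lam9)
            wc = w[:, None]
            grad += (mm_energy._acc3(n, src, wc * d_ds)
                     - mm_energy._acc3(n, tgt, wc * d_ds))
            dE_dp -= mm_energy._acc3(n, src, wc * d_dp)
            dE_dQ -= mm_energy._acc33(n, src, w[:, None, None] * d_dQ)
        # 1/2 mu A mu interaction part: -sum_{k<l} mu_k T2 mu_l
        if len(pol) > 1:
            ku, lu = np.triu_indices(len(pol), k=1)
            ki, li = pol[ku], pol[lu]
            s = coords[li] - coords[ki]
            r = np.sqrt(np.einsum("pa,pa->p", s, s))
            lam3, lam5, lam7, lam9 = thole_factors(
                r, alpha[ki], alpha[li], thole[ki], thole[li])
            g = pair_dipole_dipole_grad(s, mu[ki], mu[li], lam5, lam7)
            grad += mm_energy._acc3(n, ki, g) - mm_energy._acc3(n, li, g)
    grad += mm_energy.frame_chain_rule(coords, el, dE_dp, dE_dQ)
    return grad


def total_gradient(state: ScfState, system: QmmmSystem) -> np.ndarray:
    """Forces on all atoms from the converged variational state.

    Because (P, mu) minimize the functional, only explicit coordinate
    derivatives contribute; the result matches central finite differences of
    the total energy to machine precision on surrogate systems.
    """
    if not state.converged:
        raise ConvergenceError("refusing to differentiate an unconverged "
                               "SCF state", state.trace)
    if "forces" not in state._cache:
        fresh = scf_mutual_polarization(system, state.coords, guess=state.mu,
                                        tol=system.scf_tol, want_forces=True)
        state._cache["forces"] = fresh._cache["forces"]
    return state._cache["forces"]
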