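"""Induced point dipoles: Thole-damped mutual polarization.

The induced dipoles mu minimize the convex quadratic functional

    E_pol(mu) = 1/2 mu.T mu - mu.E_total,

where T has alpha^-1 on the (isotropic) diagonal and damped dipole-dipole
interaction blocks off the diagonal; at the minimum E_pol = -1/2 mu.E_total.
Damping follows Thole's exponential-cube screening with the pair factor
min(a_i, a_j) and screening length (alpha_i alpha_j)^(1/6).

Solvers: dense direct (oracle), preconditioned conjugate gradient, and
Jacobi/DIIS; convergence is measured as the RMS dipole change per site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.linalg

from ._kernels import thole_factors
from .errors import ConvergenceError

__all__ = [
    "PolarizationState",
    "TholeOperator",
    "build_thole_interaction",
    "solve_induced_dipoles",
    "polarization_energy",
]

DEFAULT_TOL = 1e-8
MAX_ITER = 200


@dataclass
class TholeOperator:
    """Dense damped interaction operator over the polarizable sites.

    ``matrix`` is (3m, 3m) with alpha^-1 I_3 diagonal blocks and -T2^damped
    off-diagonal blocks; ``site_index`` maps rows/3 back to atom indices.
    """

    matrix: np.ndarray
    site_index: np.ndarray
    alpha: np.ndarray

    @property
    def n_sites(self):
        return len(self.site_index)

    def apply(self, mu_flat):
        return self.matrix @ mu_flat


def build_thole_interaction(coords_bohr, alpha, thole,
                            site_index: Optional[np.ndarray] = None) -> TholeOperator:
    """Assemble the symmetric polarization operator T for sites with alpha>0.

    Coincident polarizable sites raise an error (the dipole tensor diverges).
    """
    coords = np.asarray(coords_bohr)
    alpha = np.asarray(alpha, dtype=float)
    if site_index is None:
        site_index = np.nonzero(alpha > 0)[0]
    site_index = np.asarray(site_index, dtype=int)
    m = len(site_index)
    a = alpha[site_index]
    if np.any(a <= 0):
        raise ValueError("all selected polarizable sites need alpha > 0")
    th = np.asarray(thole, dtype=float)[site_index]
    x = coords[site_index]

    A = np.zeros((3 * m, 3 * m))
    idx = np.arange(3 * m)
    A[idx, idx] = np.repeat(1.0 / a, 3)
    if m > 1:
        iu, ju = np.triu_indices(m, k=1)
        s = x[ju] - x[iu]
        r2 = np.einsum("pa,pa->p", s, s)
        if np.any(r2 < 1e-20):
            raise ZeroDivisionError("coincident polarizable sites")
        r = np.sqrt(r2)
        lam3, lam5, lam7, lam9 = thole_factors(r, a[iu], a[ju], th[iu], th[ju])
        ir3 = r ** -3
        ir5 = r ** -5
        # damped dipole field tensor T2^d
        T2 = (3.0 * lam5[:, None, None] * np.einsum("pa,pb->pab", s, s)
              * ir5[:, None, None])
        T2 -= (lam3 * ir3)[:, None, None] * np.eye(3)
        A4 = A.reshape(m, 3, m, 3)
        A4[iu, :, ju, :] = -T2
        A4[ju, :, iu, :] = -T2
    return TholeOperator(A, site_index, a)


@dataclass
class PolarizationState:
    """Converged (or partially converged) induced-dipole solution."""

    mu: np.ndarray              # (m, 3)
    field: np.ndarray           # (m, 3) total driving field E_perm + E_qm
    operator: TholeOperator
    residual: float
    iterations: int
    converged: bool
    method: str
    e_perm: Optional[np.ndarray] = None
    e_qm: Optional[np.ndarray] = None
    history: list = field(default_factory=list)


def _rms(v):
    return float(np.sqrt(np.mean(np.sum(v.reshape(-1, 3) ** 2, axis=1))))


def solve_induced_dipoles(operator: TholeOperator, e_total,
                          method: str = "cg", tol: float = DEFAULT_TOL,
                          guess=None, max_iter: int = MAX_ITER,
                          e_perm=None, e_qm=None) -> PolarizationState:
    """Solve T mu = E_total for the induced dipoles.

    ``method``: 'dense' (direct solve; the reference oracle), 'cg'
    (Jacobi-preconditioned conjugate gradient) or 'jacobi' (damped Jacobi with
    DIIS acceleration).  Convergence: RMS dipole change per site <= tol (a.u.).
    """
    m = operator.n_sites
    E = np.asarray(e_total, dtype=float).reshape(3 * m)
    A = operator.matrix
    history = []

    if m == 0 or not np.any(E):
        mu = np.zeros(3 * m)
        return PolarizationState(mu.reshape(-1, 3), E.reshape(-1, 3), operator,
                                 0.0, 0, True, method, e_perm, e_qm, history)

    if method == "dense":
        mu = scipy.linalg.solve(A, E, assume_a="sym")
        res = _rms(A @ mu - E)
        return PolarizationState(mu.reshape(-1, 3), E.reshape(-1, 3), operator,
                                 res, 1, True, method, e_perm, e_qm, history)

    alpha3 = np.repeat(operator.alpha, 3)
    mu = np.zeros(3 * m) if guess is None else np.asarray(guess, float).reshape(3 * m).copy()

    if method == "cg":
        r = E - A @ mu
        z = alpha3 * r
        p = z.copy()
        rz = r @ z
        for it in range(1, max_iter + 1):
            Ap = A @ p
            denom = p @ Ap
            if denom <= 0:
                raise ConvergenceError("polarization operator not positive "
                                       "definite along search direction", history)
            step = rz / denom
            dmu = step * p
            mu += dmu
            r -= step * Ap
            z = alpha3 * r
            # preconditioned residual = the dipole change a further relaxation
            # step would make (the per-site RMS convergence measure)
            change = _rms(z)
            history.append(change)
            if change <= tol:
                return PolarizationState(mu.reshape(-1, 3), E.reshape(-1, 3),
                                         operator, _rms(A @ mu - E), it, True,
                                         method, e_perm, e_qm, history)
            rz_new = r @ z
            p = z + (rz_new / rz) * p
            rz = rz_new
        raise ConvergenceError(
            f"induced dipoles did not converge in {max_iter} CG iterations "
            f"(last change {history[-1]:.2e})", history)

    if method == "jacobi":
        diis_mu, diis_res = [], []
        for it in range(1, max_iter + 1):
            r = E - A @ mu
            new = mu + alpha3 * r
            diis_mu.append(new.copy())
            diis_res.append((new - mu).copy())
            if len(diis_mu) > 6:
                diis_mu.pop(0)
                diis_res.pop(0)
            if len(diis_mu) > 1:
                k = len(diis_res)
                B = np.empty((k + 1, k + 1))
                B[:k, :k] = np.array([[ri @ rj for rj in diis_res]
                                      for ri in diis_res])
                B[k, :] = -1.0
                B[:, k] = -1.0
                B[k, k] = 0.0
                rhs = np.zeros(k + 1)
                rhs[k] = -1.0
                try:
                    c = np.linalg.solve(B, rhs)[:k]
                    new = sum(ci * mi for ci, mi in zip(c, diis_mu))
                except np.linalg.LinAlgError:
                    pass
            change = _rms(new - mu)
            history.append(change)
            mu = new
            if change <= tol:
                return PolarizationState(mu.reshape(-1, 3), E.reshape(-1, 3),
                                         operator, _rms(A @ mu - E), it, True,
                                         method, e_perm, e_qm, history)
        raise ConvergenceError(
            f"induced dipoles did not converge in {max_iter} Jacobi/DIIS "
            f"iterations (last change {history[-1]:.2e})", history)

    raise ValueError(f"unknown polarization solver '{method}'")


def polarization_energy(state: PolarizationState) -> float:
    """Variational polarization energy.

    At convergence this equals -1/2 mu.E_total; for an unconverged mu the
    functional value 1/2 mu.T mu - mu.E_total is returned, which upper-bounds
    the converged energy.
    """
    mu = state.mu.reshape(-1)
    E = state.field.reshape(-1)
    if state.converged:
        return float(-0.5 * mu @ E)
    A = state.operator.matrix
    return float(0.5 * mu @ (A @ mu) - mu @ E)


def static_field(gm, coords_bohr, alpha, thole, field_mask,
                 site_index=None):
    """Thole-damped, group-masked field of the permanent multipoles at the
    polarizable sites.  Returns (m, 3) aligned with ``site_index``."""
    from ._kernels import pair_field  # local import to avoid cycle noise

    coords = np.asarray(coords_bohr)
    alpha = np.asarray(alpha, float)
    if site_index is None:
        site_index = np.nonzero(alpha > 0)[0]
    site_index = np.asarray(site_index, int)
    n = len(coords)
    m = len(site_index)
    F = np.zeros((m, 3))
    if m == 0:
        return F
    # ordered (source, target) pairs for all sources vs polarizable targets
    src = np.repeat(np.arange(n), m)
    tgt = np.tile(site_index, n)
    keep = src != tgt
    src, tgt = src[keep], tgt[keep]
    w = field_mask[src, tgt]
    act = w != 0
    src, tgt, w = src[act], tgt[act], w[act]
    s = coords[tgt] - coords[src]
    r = np.sqrt(np.einsum("pa,pa->p", s, s))
    th = np.asarray(thole, float)
    lam3, lam5, lam7, _ = thole_factors(r, alpha[src], alpha[tgt],
                                        th[src], th[tgt])
    f = pair_field(s, gm.charge[src], gm.dipole[src], gm.quad[src],
                   lam3, lam5, lam7)
    pos = np.searchsorted(site_index, tgt)
    np.add.at(F, pos, w[:, None] * f)
    return F
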