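"""Vectorized pair kernels for multipolar electrostatics and polarization.

All quantities in atomic units.  Conventions:

* pair separation ``s = r_j - r_i`` (source ``i`` -> target ``j``);
* stored quadrupoles Q are traceless with pair potential V = Q:ss / r^5;
* interaction tensors T^(n) are derivatives of 1/r with respect to the target
  coordinates; Thole damping multiplies the r^-(2m+1) structural pieces by
  lambda_{2m+1} with the exponential-cube screening
  lambda_3 = 1 - exp(-a u^3), u = r/(alpha_i alpha_j)^(1/6),
  and the family is closed under differentiation (lambda_5 = lambda_3 - d e^-d
  with d = a u^3, etc.), so gradients use the next-order damped tensor.

Every function is vectorized over a leading pair axis.
"""

from __future__ import annotations

import numpy as np


def thole_factors(r, alpha_i, alpha_j, thole_i, thole_j):
    """Damping scalars (lam3, lam5, lam7, lam9) for each pair.

    Pairs where either polarizability vanishes are undamped (lambda = 1).
    """
    lam3 = np.ones_like(r)
    lam5 = np.ones_like(r)
    lam7 = np.ones_like(r)
    lam9 = np.ones_like(r)
    prod = alpha_i * alpha_j
    act = prod > 0
    if np.any(act):
        a = np.minimum(thole_i, thole_j)[act]
        u3 = (r[act] ** 3) / np.sqrt(prod[act])
        d = a * u3
        ex = np.exp(-d)
        lam3[act] = 1.0 - ex
        lam5[act] = 1.0 - (1.0 + d) * ex
        lam7[act] = 1.0 - (1.0 + d + 0.6 * d * d) * ex
        lam9[act] = 1.0 - (1.0 + d + (18.0 / 35.0) * d * d
                           + (9.0 / 35.0) * d ** 3) * ex
    return lam3, lam5, lam7, lam9


def _inv_powers(s):
    r2 = np.einsum("pa,pa->p", s, s)
    r = np.sqrt(r2)
    ir = 1.0 / r
    ir2 = ir * ir
    return r, ir, ir2


def pair_multipole_energy(s, qi, qj, pi, pj, Qi, Qj, grad=True):
    """Permanent multipole pair energy through quadrupole-quadrupole order.

    Returns ``(E, dE_ds, dE_dpi, dE_dpj, dE_dQi, dE_dQj)`` per pair (the
    derivative entries are None when ``grad`` is False).  ``dE_ds`` is the
    derivative with respect to the target position r_j (force on j = -dE_ds
    after masking; force on i = +dE_ds).
    """
    r, ir, ir2 = _inv_powers(s)
    ir3 = ir * ir2
    ir5 = ir3 * ir2
    ir7 = ir5 * ir2
    ir9 = ir7 * ir2
    ir11 = ir9 * ir2

    pis = np.einsum("pa,pa->p", pi, s)
    pjs = np.einsum("pa,pa->p", pj, s)
    pipj = np.einsum("pa,pa->p", pi, pj)
    Qis = np.einsum("pab,pb->pa", Qi, s)
    Qjs = np.einsum("pab,pb->pa", Qj, s)
    sQis = np.einsum("pa,pa->p", Qis, s)
    sQjs = np.einsum("pa,pa->p", Qjs, s)
    piQjs = np.einsum("pa,pa->p", pi, Qjs)
    pjQis = np.einsum("pa,pa->p", pj, Qis)
    QisQjs = np.einsum("pa,pa->p", Qis, Qjs)
    trQiQj = np.einsum("pab,pab->p", Qi, Qj)

    E = (qi * qj * ir
         + ir3 * (qj * pis - qi * pjs)
         + pipj * ir3 - 3.0 * pis * pjs * ir5
         + qi * sQjs * ir5 + qj * sQis * ir5
         + 5.0 * sQjs * pis * ir7 - 2.0 * piQjs * ir5
         - 5.0 * sQis * pjs * ir7 + 2.0 * pjQis * ir5
         + (35.0 / 3.0) * sQis * sQjs * ir9
         - (20.0 / 3.0) * QisQjs * ir7
         + (2.0 / 3.0) * trQiQj * ir5)

    if not grad:
        return E, None, None, None, None, None

    c = lambda x: x[:, None]  # noqa: E731 - broadcast helper

    dE = -qi[:, None] * qj[:, None] * s * c(ir3)
    # charge-dipole
    dE += (-3.0 * c(ir5) * c(qj * pis - qi * pjs) * s
           + c(ir3) * (qj[:, None] * pi - qi[:, None] * pj))
    # dipole-dipole
    dE += (-3.0 * c(pipj * ir5) * s
           - 3.0 * c(ir5) * (c(pis) * pj + c(pjs) * pi)
           + 15.0 * c(pis * pjs * ir7) * s)
    # charge-quadrupole
    dE += (qi[:, None] * (2.0 * Qjs * c(ir5) - 5.0 * c(sQjs * ir7) * s)
           + qj[:, None] * (2.0 * Qis * c(ir5) - 5.0 * c(sQis * ir7) * s))
    # dipole-quadrupole
    dE += (5.0 * c(ir7) * (2.0 * c(pis) * Qjs + c(sQjs) * pi)
           - 35.0 * c(sQjs * pis * ir9) * s
           - 2.0 * np.einsum("pab,pb->pa", Qj, pi) * c(ir5)
           + 10.0 * c(piQjs * ir7) * s
           - 5.0 * c(ir7) * (2.0 * c(pjs) * Qis + c(sQis) * pj)
           + 35.0 * c(sQis * pjs * ir9) * s
           + 2.0 * np.einsum("pab,pb->pa", Qi, pj) * c(ir5)
           - 10.0 * c(pjQis * ir7) * s)
    # quadrupole-quadrupole
    dE += ((70.0 / 3.0) * c(ir9) * (c(sQjs) * Qis + c(sQis) * Qjs)
           - 105.0 * c(sQis * sQjs * ir11) * s
           - (20.0 / 3.0) * c(ir7) * (np.einsum("pab,pb->pa", Qi, Qjs)
                                      + np.einsum("pab,pb->pa", Qj, Qis))
           + (140.0 / 3.0) * c(QisQjs * ir9) * s
           - (10.0 / 3.0) * c(trQiQj * ir7) * s)

    dE_dpi = (qj[:, None] * s * c(ir3) + pj * c(ir3) - 3.0 * c(pjs * ir5) * s
              + 5.0 * c(sQjs * ir7) * s - 2.0 * Qjs * c(ir5))
    dE_dpj = (-qi[:, None] * s * c(ir3) + pi * c(ir3) - 3.0 * c(pis * ir5) * s
              - 5.0 * c(sQis * ir7) * s + 2.0 * Qis * c(ir5))

    ss = np.einsum("pa,pb->pab", s, s)
    dE_dQi = (c(qj * ir5)[..., None] * ss
              - 5.0 * c(pjs * ir7)[..., None] * ss
              + 2.0 * np.einsum("pa,pb->pab", pj, s) * c(ir5)[..., None]
              + (35.0 / 3.0) * c(sQjs * ir9)[..., None] * ss
              - (20.0 / 3.0) * np.einsum("pa,pb->pab", Qjs, s) * c(ir7)[..., None]
              + (2.0 / 3.0) * Qj * c(ir5)[..., None])
    dE_dQj = (c(qi * ir5)[..., None] * ss
              + 5.0 * c(pis * ir7)[..., None] * ss
              - 2.0 * np.einsum("pa,pb->pab", pi, s) * c(ir5)[..., None]
              + (35.0 / 3.0) * c(sQis * ir9)[..., None] * ss
              - (20.0 / 3.0) * np.einsum("pa,pb->pab", Qis, s) * c(ir7)[..., None]
              + (2.0 / 3.0) * Qi * c(ir5)[..., None])
    return E, dE, dE_dpi, dE_dpj, dE_dQi, dE_dQj


def pair_field(s, q, p, Q, lam3, lam5, lam7):
    """Thole-damped electric field at the target from source multipoles.

    ``s = r_target - r_source``; returns (npair, 3).
    """
    r, ir, ir2 = _inv_powers(s)
    ir3 = ir * ir2
    ir5 = ir3 * ir2
    ir7 = ir5 * ir2
    ps = np.einsum("pa,pa->p", p, s)
    Qs = np.einsum("pab,pb->pa", Q, s)
    sQs = np.einsum("pa,pa->p", Qs, s)
    c = lambda x: x[:, None]  # noqa: E731
    return (c(lam3 * q * ir3) * s
            - c(lam3 * ir3) * p
            + 3.0 * c(lam5 * ps * ir5) * s
            - 2.0 * c(lam5 * ir5) * Qs
            + 5.0 * c(lam7 * sQs * ir7) * s)


def pair_mu_dot_field_grad(s, q, p, Q, mu, lam3, lam5, lam7, lam9):
    """Derivatives of mu . F(s) for a damped permanent-multipole field.

    Returns ``(d_ds, d_dq, d_dp, d_dQ)``: ``d_ds`` is with respect to the
    target position (d/dr_source = -d_ds); the rest are with respect to the
    source charge/dipole/quadrupole (for the frame chain rule).
    """
    r, ir, ir2 = _inv_powers(s)
    ir3 = ir * ir2
    ir5 = ir3 * ir2
    ir7 = ir5 * ir2
    ir9 = ir7 * ir2
    ps = np.einsum("pa,pa->p", p, s)
    mus = np.einsum("pa,pa->p", mu, s)
    mup = np.einsum("pa,pa->p", mu, p)
    Qs = np.einsum("pab,pb->pa", Q, s)
    sQs = np.einsum("pa,pa->p", Qs, s)
    muQs = np.einsum("pa,pa->p", mu, Qs)
    Qmu = np.einsum("pab,pb->pa", Q, mu)
    c = lambda x: x[:, None]  # noqa: E731

    d_ds = (-q[:, None] * (3.0 * c(lam5 * mus * ir5) * s - c(lam3 * ir3) * mu)
            - 15.0 * c(lam7 * ps * mus * ir7) * s
            + 3.0 * c(lam5 * ir5) * (c(mus) * p + c(ps) * mu + c(mup) * s)
            - 35.0 * c(lam9 * sQs * mus * ir9) * s
            + 5.0 * c(lam7 * ir7) * (2.0 * c(mus) * Qs + 2.0 * c(muQs) * s
                                     + c(sQs) * mu)
            - 2.0 * c(lam5 * ir5) * Qmu)
    d_dq = lam3 * mus * ir3
    d_dp = -c(lam3 * ir3) * mu + 3.0 * c(lam5 * mus * ir5) * s
    d_dQ = (-2.0 * c(lam5 * ir5)[..., None] * np.einsum("pa,pb->pab", mu, s)
            + 5.0 * c(lam7 * mus * ir7)[..., None] * np.einsum("pa,pb->pab", s, s))
    return d_ds, d_dq, d_dp, d_dQ


def pair_dipole_dipole(s, mu_i, mu_j, lam3, lam5):
    """mu_i . T2^damped . mu_j for each pair (the mutual-induction coupling)."""
    r, ir, ir2 = _inv_powers(s)
    ir3 = ir * ir2
    ir5 = ir3 * ir2
    mis = np.einsum("pa,pa->p", mu_i, s)
    mjs = np.einsum("pa,pa->p", mu_j, s)
    mimj = np.einsum("pa,pa->p", mu_i, mu_j)
    return 3.0 * lam5 * mis * mjs * ir5 - lam3 * mimj * ir3


def pair_dipole_dipole_grad(s, mu_i, mu_j, lam5, lam7):
    """d/ds of mu_i . T2^damped . mu_j (uses the damped T3 tensor)."""
    r, ir, ir2 = _inv_powers(s)
    ir5 = ir ** 5
    ir7 = ir5 * ir2
    mis = np.einsum("pa,pa->p", mu_i, s)
    mjs = np.einsum("pa,pa->p", mu_j, s)
    mimj = np.einsum("pa,pa->p", mu_i, mu_j)
    c = lambda x: x[:, None]  # noqa: E731
    return (-15.0 * c(lam7 * mis * mjs * ir7) * s
            + 3.0 * c(lam5 * ir5) * (c(mis) * mu_j + c(mjs) * mu_i + c(mimj) * s))


def buffered_14_7(r, rmin, eps, delta=0.07, gamma=0.12):
    """Halgren buffered 14-7 pair energy and dE/dr.

    E = eps * ((1+delta)/(rho+delta))^7 * ((1+gamma)/(rho^7+gamma) - 2),
    rho = r / rmin.  The minimum is at rho = 1 with depth -eps.
    """
    rho = r / rmin
    t1 = ((1.0 + delta) / (rho + delta)) ** 7
    rho7 = rho ** 7
    t2 = (1.0 + gamma) / (rho7 + gamma)
    E = eps * t1 * (t2 - 2.0)
    dt1 = -7.0 * t1 / (rho + delta)
    dt2 = -t2 / (rho7 + gamma) * 7.0 * rho ** 6
    dE_drho = eps * (dt1 * (t2 - 2.0) + t1 * dt2)
    return E, dE_drho / rmin
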