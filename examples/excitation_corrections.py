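"""Polarizable-environment contributions to electronic excitations.

The excited-state solver (a TDDFT backend in production; synthetic fields
here) supplies electric fields of transition densities at the polarizable MM
sites.  This package returns (i) the induced-dipole response coupling that
dresses the excitation matrices during the iterative eigensolve and (ii) the
state-specific corrected-linear-response (c-LR) shift from the relaxed
difference density, always red (non-positive).
"""

import numpy as np

from polqmmm import fixtures, polarization, response, units

cloud = fixtures.make_multipole_cloud(30, seed=6)
operator = polarization.build_thole_interaction(cloud.coords, cloud.alpha,
                                                cloud.thole)

f_transition = fixtures.make_transition_fields(30, seed=1, scale=5e-3)
f_difference = fixtures.make_transition_fields(30, seed=2, scale=5e-3)

coupling = response.environment_response_contribution(
    f_transition, f_transition, operator)
shift = response.clr_correction(f_difference, operator)

e_uncorrected = 3.05  # eV, from the excited-state solver
print(f"{operator.n_sites} polarizable environment sites")
print(f"response matrix element -mu(f).f = {coupling:+.6e} hartree")
print(f"  (the diagonal dressing added to the excitation matrices; its")
print(f"   symmetry value(x,y) = value(y,x) is exact by self-adjointness)")
print(f"c-LR state-specific shift        = {shift:+.6f} eV (always <= 0)")
print(f"corrected excitation energy      = {e_uncorrected + shift:.4f} eV "
      f"(uncorrected {e_uncorrected:.4f} eV)")

# single-site closed form: -1/2 alpha |E|^2
op1 = polarization.build_thole_interaction(
    np.zeros((1, 3)), np.array([2.0]), np.array([0.39]))
E = np.array([[0.01, 0.0, 0.0]])
print(f"single-site check: clr = {response.clr_correction(E, op1):.3e} eV, "
      f"closed form {-0.5*2.0*1e-4*units.EV_PER_HARTREE:.3e} eV")
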