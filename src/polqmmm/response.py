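"""Environment contributions to electronic excitations.

The backend solving the Casida equations calls these hooks each iteration:

* :func:`environment_response_contribution` supplies the induced-dipole
  response matrix element that dresses the coupling matrices: for transition-
  density fields x, y at the polarizable sites it returns -mu(x).y, where
  mu(x) solves the damped polarization equations.  The polarization operator
  is self-adjoint, so the value is symmetric in x <-> y.

* :func:`clr_correction` is the state-specific (corrected linear response)
  shift: the relaxed excited-minus-ground difference density's field E_D
  interacts with the dipoles it itself induces, giving -1/2 mu(E_D).E_D,
  always non-positive for a positive-definite polarization operator.

All inputs are electric fields at the polarizable MM sites (a.u.), never
densities, so the module stays free of basis-set machinery and synthetic
fields test it exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from . import units
from .polarization import TholeOperator

__all__ = [
    "TransitionDensityField",
    "ExcitationResult",
    "environment_response_contribution",
    "clr_correction",
]


@dataclass
class TransitionDensityField:
    """Field of a transition (or relaxed difference) density at the
    polarizable sites, with provenance tag {backend, surrogate, synthetic}."""

    label: str
    field: np.ndarray        # (m, 3) a.u.
    provenance: str = "synthetic"

    def __post_init__(self):
        self.field = np.asarray(self.field, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.field)):
            raise ValueError(f"non-finite transition field '{self.label}'")


@dataclass
class ExcitationResult:
    """Excitation energy bookkeeping (eV)."""

    label: str
    energy_eV: float
    response_eV: float
    clr_eV: float

    @property
    def corrected_eV(self) -> float:
        return self.energy_eV + self.clr_eV


def _solve(operator: TholeOperator, f):
    return scipy.linalg.solve(operator.matrix, np.asarray(f, float).reshape(-1),
                              assume_a="sym")


def environment_response_contribution(field_x, field_y,
                                      operator: TholeOperator) -> float:
    """Induced-dipole response coupling -mu(field_x) . field_y (hartree).

    Symmetric under x <-> y because T^-1 is self-adjoint.
    """
    fx = np.asarray(field_x, dtype=float).reshape(-1)
    fy = np.asarray(field_y, dtype=float).reshape(-1)
    if fx.shape != fy.shape or len(fx) != 3 * operator.n_sites:
        raise ValueError("fields must cover every polarizable site")
    if not np.any(fx) or not np.any(fy):
        return 0.0
    mu = _solve(operator, fx)
    return float(-mu @ fy)


def clr_correction(difference_field, operator: TholeOperator) -> float:
    """State-specific correction -1/2 mu(E_D).E_D in eV (non-positive).

    ``difference_field`` is the relaxed excited-minus-ground density's field
    at the polarizable sites.
    """
    f = np.asarray(difference_field, dtype=float).reshape(-1)
    if len(f) != 3 * operator.n_sites:
        raise ValueError("field must cover every polarizable site")
    if not np.any(f):
        return 0.0
    mu = _solve(operator, f)
    return float(-0.5 * (mu @ f) * units.EV_PER_HARTREE)
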