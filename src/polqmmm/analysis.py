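"""Trajectory and property analyses: dihedral distributions with Gaussian
fits, bond-length alternation (BLA), excitation-structure correlations, and
energy-conservation reports."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .dynamics import drift_stats
from .errors import ValidationError

__all__ = [
    "BlaSpec",
    "dihedral",
    "dihedral_series",
    "histogram_gaussian_fit",
    "bla",
    "pearson_corr",
    "energy_timeseries_report",
]


@dataclass
class BlaSpec:
    """Ordered bonds along a conjugated path, tagged formal-single or
    formal-double.  BLA = mean(single lengths) - mean(double lengths), so an
    inverted alternation pattern gives negative values."""

    single_bonds: list   # [(i, j), ...] 0-based
    double_bonds: list

    def __post_init__(self):
        if len(self.single_bonds) + len(self.double_bonds) < 2 \
                or not self.single_bonds or not self.double_bonds:
            raise ValidationError(
                "BLA needs at least one formal-single and one formal-double bond")


def dihedral(coords, i, j, k, l):
    """Signed dihedral angle (degrees) in (-180, 180], IUPAC convention:
    cis (eclipsed) = 0, trans (anti) = 180."""
    coords = np.asarray(coords)
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nn = np.linalg.norm(n1) * np.linalg.norm(n2)
    if nn < 1e-12:
        raise ValidationError(
            f"dihedral {i}-{j}-{k}-{l} undefined: collinear middle bond")
    cos = np.dot(n1, n2) / nn
    sin = np.dot(np.cross(n1, n2), b2) / (nn * np.linalg.norm(b2))
    ang = np.degrees(np.arctan2(sin, cos))
    return 180.0 if np.isclose(ang, -180.0) else float(ang)


def dihedral_series(trajectory, i, j, k, l):
    """Dihedral angle per frame (degrees) for a (n_frames, n_atoms, 3) array
    or an iterable of coordinate frames."""
    if len({i, j, k, l}) != 4:
        raise ValidationError("dihedral needs four distinct atoms")
    return np.array([dihedral(frame, i, j, k, l) for frame in trajectory])


def histogram_gaussian_fit(series, bins=None, bin_width=1.0, density=False,
                           r2_threshold=0.8):
    """Least-squares Gaussian fit to the histogram of a series.

    Returns mean, sigma, amplitude, the histogram, an R^2 diagnostic and a
    ``poor_fit`` flag (multimodal or otherwise non-Gaussian series).  Both
    count and density normalizations are available via ``density``.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 10:
        raise ValidationError("need at least 10 samples for a histogram fit")
    if np.std(x) == 0:
        raise ValidationError("zero-variance series cannot be fitted")
    if bins is None:
        lo, hi = x.min(), x.max()
        pad = bin_width
        bins = np.arange(lo - pad, hi + 2 * pad, bin_width)
    counts, edges = np.histogram(x, bins=bins, density=density)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def gauss(t, amp, mu, sig):
        return amp * np.exp(-0.5 * ((t - mu) / sig) ** 2)

    p0 = (counts.max(), x.mean(), max(x.std(), 1e-3))
    try:
        popt, _ = curve_fit(gauss, centers, counts, p0=p0, maxfev=10000)
    except RuntimeError:
        popt = p0
    amp, mu, sig = popt
    resid = counts - gauss(centers, *popt)
    ss_tot = float(np.sum((counts - counts.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 0.0
    return {
        "mean": float(mu),
        "sigma": float(abs(sig)),
        "amplitude": float(amp),
        "histogram": (counts, edges),
        "r_squared": r2,
        "poor_fit": r2 < r2_threshold,
    }


def bla(frame, spec: BlaSpec, coords_in_angstrom=True):
    """Bond length alternation of one frame, in picometres.

    mean(formal-single lengths) - mean(formal-double lengths); inputs in
    Angstrom by default (1 A = 100 pm).
    """
    coords = np.asarray(frame)
    n = len(coords)

    def length(b):
        i, j = b
        if not (0 <= i < n and 0 <= j < n):
            raise ValidationError(f"BLA bond {b} references a missing atom")
        return np.linalg.norm(coords[j] - coords[i])

    singles = np.mean([length(b) for b in spec.single_bonds])
    doubles = np.mean([length(b) for b in spec.double_bonds])
    factor = 100.0 if coords_in_angstrom else 100.0 * 0.529177210903
    return float((singles - doubles) * factor)


def pearson_corr(x_series, y_series):
    """Sample Pearson correlation coefficient in [-1, 1]."""
    x = np.asarray(x_series, dtype=float)
    y = np.asarray(y_series, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("need two equal-length series with >= 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("correlation undefined for a constant series")
    return float(np.corrcoef(x, y)[0, 1])


def energy_timeseries_report(energy_series, timestep_fs, offset_mEh=0.0):
    """Mean-shifted energy series (milli-hartree) plus drift statistics.

    Mirrors the presentation of NVE conservation traces: each series is
    shifted by its own trajectory average, optionally offset vertically for
    stacked plotting.
    """
    e = np.asarray(energy_series, dtype=float)
    shifted_mEh = (e - e.mean()) * 1e3 + offset_mEh
    stats = drift_stats(e, timestep_fs)
    stats["max_abs_dev_mEh"] = stats["max_abs_dev_from_mean"] * 1e3
    return {
        "shifted_mEh": shifted_mEh,
        "time_ps": np.arange(len(e)) * timestep_fs * 1e-3,
        "drift": stats,
    }
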