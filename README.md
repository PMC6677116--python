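# polqmmm

Polarizable, multipolar QM/MM embedding with pseudobond covalent boundaries,
mutual QM–MM polarization, NVE Born–Oppenheimer dynamics with
extended-Lagrangian SCF guess propagation, and polarizable-embedding
corrections to electronic excitations.

## Who this is for

Developers and students of hybrid quantum/classical methods who need a
*verifiable* implementation of the coupling layer between an electronic
structure code and an AMOEBA-style polarizable force field: boundary
bookkeeping across cut covalent bonds, the self-consistent induced-dipole /
density loop, analytic forces good enough for microcanonical dynamics, and
the environment operators entering excited-state calculations.  The
electronic-structure solver itself is *not* included: a backend contract is
defined, and a classical **surrogate backend** (whose "density" is its own
induced-dipole set) makes every coupled quantity exactly checkable against
dense linear-algebra oracles at desk scale.

## The model

The energy is the variational functional

    E(P, μ) = E_qm[P] + E_ele[P] + E_pol[P, μ] + E_mm[μ]

minimized simultaneously in the density `P` and the classical induced dipoles
`μ`.  The classical engine provides AMOEBA-form permanent multipoles through
quadrupoles in local frames, Thole-damped mutual polarization
(`λ₃ = 1 − e^{−a u³}`, `u = r/(αᵢαⱼ)^{1/6}`), Halgren's buffered 14-7
dispersion–repulsion, and the full valence series (anharmonic bond/angle,
stretch–bend, out-of-plane, torsion, π-torsion, torsion–torsion maps).

Cut σ-bonds are handled by the pseudobond scheme: the boundary atom joins the
QM region as a one-free-valence atom described by a parameterizable
one-Gaussian ECP + four-parameter minimal basis; classically, the multipoles
and polarizabilities of its MM neighbours (MM1) are zeroed, their monopoles
moved — split equally — onto the next shell (MM2) so total charge is
conserved exactly, and valence terms straddling the boundary are kept
classical.  A hydrogen link-atom alternative is provided.

See `docs/methods.md` for the full model description, conventions and
limitations.

## Worked example

A pseudobond-cut amide chain in a droplet of polarizable water, with the
surrogate backend on the QM side (`examples/single_point_energy.py`):

```
83 atoms (13 QM); SCF converged in 6 macro-cycles
E_qm_internal = +1.78665858 hartree (backend internal energy)
E_ele_env     = +0.01891114 hartree (QM-MM static electrostatics + buffered 14-7)
E_pol_env     = -0.00106793 hartree (joint induced-dipole energy, always <= 0 at the minimum)
E_mm          = +1.30344170 hartree (classical valence + MM-MM nonbonded, incl. hybrid terms)
E_total       = +3.10794349 hartree
decomposition closure: 0.00e+00 (exact by construction)
net force on the system: 8.10e-16 a.u. (translational invariance)
```

The four components are the terms of the variational functional; the
polarization energy is negative because the induced dipoles minimize a
positive-definite quadratic form, and the component sum closes on `E_total`
exactly because the decomposition is constructed from the same pair sums.
A short NVE run of the same kind of system (`examples/droplet_dynamics.py`)
prints the conservation diagnostics:

```
0.1 ps NVE at 80 K, dt = 0.5 fs:
  drift slope      = +9.561e-06 hartree/ps
  max |E - <E>|    = 0.0575 mEh
  rms fluctuation  = 0.0144 mEh
  mean SCF macro-cycles/step = 4.79
```

Sub-0.1 mEh deviations about a flat mean are the signature that analytic
forces and the integrator are mutually consistent.  The other examples cover
boundary bookkeeping (`partition_boundary.py`), excitation corrections
(`excitation_corrections.py`) and trajectory analyses
(`structural_analysis.py`).

## Command line

`polqmmm partition|energy|md|excite|analyze --config run.json` — a thin layer
over the library for shell workflows; every command embeds the config hash
and seed in its outputs and is re-runnable from them.  Inputs are Tinker-style
`txyz` structures, a Tinker-keyword `prm` parameter subset, and a JSON run
config (units stated in key names, e.g. `timestep_fs`).

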