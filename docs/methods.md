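# Methods

## The model

`polqmmm` implements a polarizable, multipolar QM/MM embedding on the
variational energy functional

    E(P, mu) = E_qm[P] + E_ele[P] + E_pol[P, mu] + E_mm[mu],

where `P` is the electronic density held by a backend, and `mu` are induced
point dipoles on the classical polarizable sites.  Both sets of variables are
optimized in one self-consistent loop (mutual polarization), so at
convergence the total energy is stationary in `P` and `mu`, and analytic
nuclear gradients need only the explicit coordinate derivatives — the
property that makes long microcanonical (NVE) trajectories conserve energy.

The classical side is an AMOEBA-style force field:

* permanent atomic multipoles through quadrupoles, defined in local molecular
  frames (z-then-x, bisector, z-bisector, z-only) and rotated to the global
  frame each geometry;
* one isotropic inducible dipole per polarizable site, coupled by
  Thole-damped dipole field tensors.  Damping is the exponential-cube form,
  `lambda_3 = 1 - exp(-a u^3)` with `u = r/(alpha_i alpha_j)^(1/6)` and the
  pair factor `a = min(a_i, a_j)` (default 0.39);
* Halgren's buffered 14-7 dispersion-repulsion (delta = 0.07, gamma = 0.12,
  cubic-mean r_min and HHG epsilon combining, hydrogen reduction factors);
* valence terms: anharmonic bonds (cubic/quartic), angles with higher-order
  corrections, stretch-bend coupling, Wilson-Decius-Cross out-of-plane
  bending, torsion Fourier series, 2-fold pi-torsions (our convention:
  `E = k sin^2(phi)` of the twist between the two substituent-plane normals,
  zero for any coplanar arrangement), and torsion-torsion maps interpolated
  by bicubic splines on periodically padded grids so value and slope are
  consistent across the +-180 degree seam.

Masking follows Tinker conventions: permanent electrostatics scaled 0/0/0.4/
0.8 for 1-2/1-3/1-4/1-5 pairs, vdW 0/0/1, and the permanent field that
polarizes a site is masked group-wise (sites in the same polarization group
do not polarize each other); mutual dipole-dipole coupling is unmasked but
Thole damped.  A single induced-dipole set is used (no separate direct/mutual
sets); this is a deliberate simplification relative to full AMOEBA and is the
main caveat when loading production AMOEBA parameter files.

## Covalent boundaries

When the QM region is covalently bonded to the environment, the boundary atom
of a cut sigma bond is replaced by a seven-valence-electron pseudobond (PB)
atom carried by the QM subsystem.  The electronic side of the PB atom is a
one-Gaussian effective core potential `V(r) = a exp(-b r^2)` plus a minimal
STO-2G-style basis with shared s/p exponents (four parameters); these are
empirical per boundary class (Cps-C, Cps-N, Cps-C=O) and are *not* shipped —
`EcpSpec` is a configurable record the user fills for a real backend, and the
classical surrogate ignores it.  Classically:

* MM1 atoms (bonded to a PB atom) lose their permanent multipoles and
  polarizabilities; each MM1 monopole is split equally over that MM1's MM2
  neighbours, conserving total charge exactly (equal division is the simplest
  charge-conserving rule; the boundary literature says only "distributed");
* PB atoms carry no classical multipoles or polarizabilities;
* every valence tuple containing at least one MM atom and at least one atom
  from QM∪PB is evaluated classically (the *hybrid* terms, including the
  PB-MM1 stretch); tuples fully inside QM belong to the backend, tuples fully
  inside MM to the classical remainder.  A brute-force enumeration test
  verifies that hybrid + pure-QM + pure-MM exactly partition the uncut tuple
  set.

A hydrogen link-atom alternative is provided for single points: the cap sits
at `scale * |AB|` along the cut bond (default scale 0.71, a typical C-H/C-C
ratio — the placement rule is a package choice), and the replaced MM atom's
charge is split equally over its classical neighbours.

QM-MM electrostatics is unmasked (the density sees all adjusted multipoles,
which is the point of the MM1/MM2 adjustment); QM-MM dispersion-repulsion
keeps the topological 1-2/1-3 exclusions so directly bonded boundary pairs do
not clash.  Intra-QM vdW is excluded (backend's job).

## The surrogate backend

The backend contract exposes, per QM atom, an effective charge and an
isotropic polarizability, plus flags for internal terms.  The shipped
*surrogate* backend is deliberately classical: its "density" is its own
induced-dipole set, and it retains the classical valence terms of the QM
subsystem as internal energy (without them a QM fragment would be unbound and
no dynamics would be possible).  Two properties make it the verification
vehicle for the whole coupling machinery:

* the joint QM+MM polarization problem is a single symmetric positive
  definite linear system, so the alternating backend/dipole SCF (block
  Gauss-Seidel, each block solved exactly by Cholesky) must reproduce the
  one-shot dense solution to solver precision, and the energy trace must
  decrease monotonically;
* every term is differentiable in closed form, so total forces can be held to
  finite-difference agreement at the 1e-9 a.u. level.

A real electronic-structure adapter registers under the same contract
(consuming the environment descriptor of adjusted point multipoles plus
current induced dipoles, returning density, energies, fields); none is
bundled, keeping the core free of quantum-chemistry dependencies.

## Gradients

Nonbonded gradients are analytic: interaction tensors `T^(n)` (derivatives of
1/r) through fifth order for permanent multipole pairs, and the damped tensor
family for polarization terms — the Thole lambda factors are closed under
differentiation (`d T^(n)_damped = T^(n+1)_damped`), so no extra damping
derivatives are needed.  Because the converged `(P, mu)` minimize the
functional, no response terms arise.

Two pieces are differentiated by *complex-step* differentiation (h = 1e-20),
which is exact to machine precision and independent of the real-arithmetic
finite-difference oracle used in tests: (i) the local-frame rotation map
(the torque-like forces on frame-defining atoms), vectorized per frame-atom
slot over all sites, and (ii) the valence terms, vectorized per atom slot per
term class.  Torsion-torsion terms combine analytic spline partials with
complex-step dihedral derivatives.

## Dynamics

Velocity Verlet in the NVE ensemble, timestep 0.5 fs, initial velocities
Maxwell-Boltzmann (default 80 K — low temperature keeps the energy
fluctuations small enough to resolve drifts); centre-of-mass momentum removed
at initialization only, no thermostat anywhere.  The SCF guess at each step
is propagated by the dissipative time-reversible extended-Lagrangian (XL-BO)
scheme with the standard coefficient tables for orders 3-9 (default 5),
applied to the induced dipoles and the surrogate density alike.  XL-BO
changes iteration counts, never converged energies (verified to SCF
tolerance).  The default dipole convergence is 1e-8 a.u. RMS per site; for
multi-picosecond NVE runs the package uses 1e-10: at looser tolerances the
forward-extrapolated guess leaves a small motion-correlated residual force
that dissipates energy as a systematic drift, while the fluctuation
amplitude itself is integrator physics and does not depend on the tolerance.
The drift statistics the acceptance battery reports are computed at the
tight setting.

Random packings are violently strained, so production trajectories start
from an L-BFGS-relaxed geometry followed by a short (0.25 ps) NVE
equilibration segment; this mirrors the usual preparation step of droplet
protocols and avoids the velocity-Verlet shadow-energy offset that an
atypical minimum-potential/fresh-velocity start leaves as a step-0 outlier
in `|E - <E>|`.

## Excitation hooks

The Casida-type eigenproblem belongs to the excited-state backend.  This
package supplies the two environment contributions as functions of *fields at
polarizable sites* (never densities, so synthetic testing is exact):

* response coupling `-mu(f_x) . f_y`, where `mu(f)` solves the damped
  polarization equations — symmetric in `x <-> y` by self-adjointness;
* the state-specific c-LR shift `-1/2 mu(f_D) . f_D` (in eV) for the relaxed
  excited-minus-ground difference-density field, non-positive whenever the
  polarization operator is positive definite.  The -1/2 prefactor follows
  the corrected-linear-response convention of the continuum-solvation
  literature (a convention choice; the excitation reports expose both the
  uncorrected and corrected values).

## Synthetic data

All test inputs are generated: water droplets (rigid monomers, random
placement/orientation, minimum O-O distance 2.8 A), amide-backbone chains
H2N-[CH2-CO-NH]n-H with designated pseudobond cuts on either side of an
alpha-carbon (one or two cuts), random multipole clouds (neutralized charges,
traceless quadrupoles, alpha in 2-8 bohr^3), and random transition fields.
Parameters are AMOEBA-like in form but synthetic in value, with full valence
coverage (including pi-torsion and a periodic torsion-torsion map) generated
from the actual topology so no tuple is ever unresolvable.  Fixture charges
were chosen once to be chemically plausible (amide-scale partial charges,
MM1 carbonyl carbon at +0.55 e so redistribution moves real charge); water
polarizabilities are near the literature values.  Everything is bit
reproducible under a fixed seed.

What passing on these fixtures shows: the *coupling machinery* — boundary
bookkeeping, mutual polarization, forces, conservation, response algebra —
is correct to numerical precision.  What it does not show: agreement with a
real electronic structure, real force-field accuracy, or behaviour of
full-scale solvated biomolecules; those need a production backend and real
parameter files.

## Problem sizes and numerical choices

Verification runs use desk-scale systems chosen to exercise every code path:
5 force fixtures of 12-47 atoms (all components checked against central
finite differences, step 1e-4 bohr, tolerance 1e-6 a.u.), 30-60-site
polarization clouds (dense-solve agreement to 1e-10 a.u.), a 173-atom
droplet (50 waters + cut chain) for the 2 ps NVE conservation run, and a
59-atom droplet for the 500-step XL-BO pairing.  Dense linear algebra is used
throughout (no cutoffs, no neighbour lists, no Ewald — droplet boundary
conditions, exactness first); systems beyond a few thousand polarizable sites
would need iterative matrix-free solvers, which the CG path provides but is
not tuned for.

Known limitations: single induced-dipole set (see above); no periodic
boundary conditions; the z-only frame resolves its x-axis by a deterministic
but discontinuous rule, so z-only sites should carry axially symmetric
multipoles (the fixtures do); anharmonic valence coefficient conventions are
per-radian and per-bohr internally, so real Tinker parameter files load but
their higher-order valence constants may need rescaling.
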