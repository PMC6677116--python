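"""Pseudobond boundary bookkeeping on a small amide chain.

Builds a 3-unit amide chain, cuts it at the second alpha-carbon (the PB
atom), and shows the MM1/MM2 shells, the boundary classification, the exact
charge redistribution and the hybrid valence terms that straddle the cut.
"""

import numpy as np

import polqmmm as pq
from polqmmm import ffio, fixtures

structure, params, spec = fixtures.make_pb_chain(3, 2, seed=5)
boundary = ffio.build_partition(structure, spec)

print(f"chain: {structure.n_atoms} atoms, QM region {len(spec.qm_atom_ids)} "
      f"atoms, PB atoms {sorted(spec.pb_atom_ids)}")
for pb in boundary.pb_atoms:
    print(f"PB atom {pb} ({boundary.pb_types[pb]}): "
          f"MM1 = {boundary.mm1[pb]}, "
          f"MM2 = {[boundary.mm2[m] for m in boundary.mm1[pb]]}")

atomic = ffio.assign_atomic_multipoles(structure, params)
adjusted = ffio.zero_and_redistribute(atomic, boundary)
print(f"total charge before adjustment: {atomic.total_charge():+.6f} e")
print(f"total charge after  adjustment: {adjusted.total_charge():+.6f} e")
m1 = boundary.mm1[boundary.pb_atoms[0]][0]
print(f"MM1 atom {m1}: charge {atomic.charge[m1]:+.3f} e -> "
      f"{adjusted.charge[m1]:+.3f} e (moved to MM2, split equally)")

hybrid, pure_mm, pure_qm = ffio.enumerate_boundary_valence_terms(
    structure, boundary, params)
print("hybrid valence terms (>=1 MM and >=1 QM/PB atom):")
for kind in ("bonds", "angles", "strbnd", "opbend", "torsions", "pitors",
             "tortors"):
    terms = getattr(hybrid, kind)
    if terms:
        print(f"  {kind:8s}: {len(terms):3d}  e.g. {terms[0]}")
# the PB-MM1 stretch is the only hybrid two-body term
assert hybrid.bonds == [tuple(sorted((boundary.pb_atoms[0], m1)))]
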