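"""Patient-specific connectivity as a rank-2 deviation from a population graph.

Shows the exact algebraic consistency between the two ways of building a
patient Laplacian, and the feasibility audit of perturbed edge weights.
"""

import numpy as np

from adbc import (
    LowRankPerturbation,
    build_laplacian,
    check_weight_constraints,
    patient_adjacency,
    patient_laplacian,
)
from adbc.synthetic import CohortSpec, generate_population_graph

pop = generate_population_graph(CohortSpec(n_regions=8, seed=1))
rng = np.random.default_rng(1)
u = np.zeros(8); u[[1, 4]] = rng.normal(scale=0.2, size=2)
v = np.zeros(8); v[[2, 4]] = rng.normal(scale=0.2, size=2)
pert = LowRankPerturbation(u, v)

A = patient_adjacency(pop.adjacency, pert)
L_direct = patient_laplacian(pop.laplacian, pert)
_, L_via_A = build_laplacian(np.clip(A, 0, None)) if np.all(A >= 0) else (None, None)
if L_via_A is None:
    d = A.sum(axis=1)
    L_via_A = np.diag(d) - A

print("max |direct Laplacian update - Laplacian of updated adjacency|:",
      f"{np.max(np.abs(L_direct - L_via_A)):.2e}")
print("max |row sum| of patient Laplacian:", f"{np.max(np.abs(L_direct.sum(1))):.2e}")
viol = check_weight_constraints(pop.adjacency, pert)
print("edge-weight constraint violations:", viol if viol else "none")
print()
print("The rank-2 update changes", int((np.abs(A - pop.adjacency) > 1e-12).sum() // 2),
      "edges; the two Laplacian routes agree to machine precision, so the")
print("closed-form update can be used during fitting without rebuilding the graph.")
print("This unconstrained random draw slightly undershoots one edge below 0 --")
print("exactly what the audit reports; during fitting the optimizer enforces")
print("0 <= weight <= 1 on every perturbed edge as a hard constraint.")
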