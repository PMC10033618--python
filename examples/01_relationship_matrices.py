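"""Relationship matrices for a tetraploid population.

Builds a small simulated marker panel, then the additive genomic
relationship G (VanRaden method 1 for ploidy 4), the digenic dominance
relationship D, the genomic inbreeding coefficients F, a pedigree A matrix,
and a blended H matrix.
"""

import numpy as np
import pandas as pd

import polyblup as pb

ms = pb.sim_population(n=200, m=1500, ploidy=4, seed=11)
G = pb.compute_G(ms)
dom, D = pb.compute_dominance(ms)

print(f"{ms.n} individuals x {ms.m} markers, ploidy {ms.ploidy}")
print(f"mean diagonal of G: {np.diag(G.values).mean():.3f} "
      "(1 + (phi-1) F on average; ~1 under panmixia)")
print(f"grand mean of G: {G.values.mean():.2e} (exactly 0 by centering)")

# two definitions of genomic inbreeding agree in large marker panels
F_D = dom.F
F_G = pb.inbreeding_from_diag(G, ms.ploidy)
print(f"mean F from dominance coefficients: {F_D.mean():+.4f}")
print(f"mean F from diag(G):               {F_G.mean():+.4f}")
print(f"correlation of the two definitions: {np.corrcoef(F_D, F_G)[0, 1]:.3f}")

# pedigree A for a few crosses, then H blending
ped = pd.DataFrame({
    "id": ["p1", "p2", "p3", "c1", "c2", "c3"],
    "parent1": [None, None, None, "p1", "p1", "c1"],
    "parent2": [None, None, None, "p2", "p3", "c1"],
})
A = pb.pedigree_A(ped, ploidy=4)
print("\npedigree A (tetraploid, bivalent pairing):")
print(pd.DataFrame(A.values, index=A.ids, columns=A.ids).round(3))
print("c3 is a self of c1: its diagonal exceeds 1 by (phi-1) * F =",
      round(A.values[A.ids.index('c3'), A.ids.index('c3')] - 1, 3))
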