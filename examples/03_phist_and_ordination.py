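"""Pairwise PhiST by AMOVA, a permutation test, and NMDS of the matrix.

PhiST partitions the variance of pairwise sequence differences within and
between populations; 0 means panmixia, 1 means fixed differences.  The
matrix of all pairwise values is then embedded in the plane by non-metric
multidimensional scaling.
"""

import numpy as np
import pandas as pd

from dloopkin.ordination import nmds, upgma
from dloopkin.popgen_fst import pairwise_phi_st, permutation_p

rng = np.random.default_rng(4)

# four small populations: two close, two progressively diverged
def pop(center, n=6, noise=2):
    out = []
    for _ in range(n):
        s = list(center)
        for j in rng.choice(len(s), size=noise, replace=False):
            s[j] = rng.choice(list("ACGT"))
        out.append("".join(s))
    return out

c1 = "".join(rng.choice(list("ACGT"), 60))
c2 = list(c1); c2[:4] = "TTTT"; c2 = "".join(c2)
c3 = list(c1); c3[:12] = "G" * 12; c3 = "".join(c3)
pops = {"EGYA": pop(c1), "EGYB": pop(c1), "EURO": pop(c2), "EAST": pop(c3)}

names = list(pops)
phi = pd.DataFrame(0.0, index=names, columns=names)
for i, a in enumerate(names):
    for b in names[i + 1:]:
        phi.at[a, b] = phi.at[b, a] = max(pairwise_phi_st(pops[a], pops[b]), 0.0)
print("pairwise PhiST (AMOVA on difference counts):")
print(phi.round(3))

p = permutation_p(pops["EGYA"], pops["EAST"], n_perm=999, seed=1)
print(f"\npermutation p for EGYA vs EAST: {p:.4f} "
      "(fraction of shuffles at least as differentiated)")

res = nmds(phi, seed=2, n_restarts=10)
print(f"\nNMDS coordinates (stress-1 = {res.stress:.4f}; low stress means")
print("the plane faithfully ranks the PhiST dissimilarities):")
print(res.coordinates.round(3))
print("\nUPGMA dendrogram:", upgma(phi).to_newick())
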