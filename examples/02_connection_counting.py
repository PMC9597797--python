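"""Count type-1 and type-2 phylogenetic connections on a toy tree.

A type-1 connection links the breeds of two strictly sister tips (a cherry);
a type-2 connection links a tip whose sister clade is a cherry to each
cherry tip.  The breed x breed tallies are the affinity statistic the
pipeline clusters and plots.
"""

from dloopkin.kinship_core import (
    breed_profile,
    connection_matrix,
    find_type1_pairs,
    find_type2_triples,
)
from dloopkin.tree_model import parse_newick

newick = "(((Saidi1,Sohagi1),(Sohagi2,(Fallahi1,Sohagi3))),(Barki1,Merino1));"
tree = parse_newick(newick)
breed_of = {
    "Saidi1": "SAID", "Sohagi1": "SOHA", "Sohagi2": "SOHA",
    "Fallahi1": "FALL", "Sohagi3": "SOHA", "Barki1": "BARK",
    "Merino1": "MERI",
}

print("cherries (type 1):", find_type1_pairs(tree))
print("tip-plus-cherry (type 2):", find_type2_triples(tree))

m2 = connection_matrix(tree, breed_of, kinship_type=2)
print("\ntype-2 connection matrix (diagonal = within-breed links):")
print(m2.counts)

prof = breed_profile(m2, "SOHA", retention_fraction=0.75)
print("\nSohagi partner profile (count, percent of all its links):")
for partner, (count, pct) in sorted(prof.partners.items()):
    print(f"  {partner}: {count} ({pct:.0f}%)")
print("retained partners covering >=75% of links:", prof.retained)
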