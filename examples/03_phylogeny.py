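"""Exact maximum-parsimony phylogeny from a binary presence matrix.

Leaves are tumor regions, the root is germline (no somatic mutations), and
each edge length counts the mutations assigned to it, so the drawn trunk and
branches are proportional to detected mutation numbers.
"""

import numpy as np

from mrith import (PatientMutationMatrix, build_phylogenetic_tree,
                   trunk_fraction_from_tree)

# 10 mutations x 3 regions: 5 shared by all, 3 shared by R1+R2, 2 private to R3
presence = np.array([[1, 1, 1]] * 5 + [[1, 1, 0]] * 3 + [[0, 0, 1]] * 2)
matrix = PatientMutationMatrix(
    "P1", [f"m{i}" for i in range(10)], ["R1", "R2", "R3"], presence)

tree = build_phylogenetic_tree(matrix)
print("newick:          ", tree.to_newick())
print("parsimony score: ", tree.parsimony_score)
print("trunk length:    ", tree.trunk_length)
print("trunk fraction:  ", trunk_fraction_from_tree(tree))
print("pattern:         ", tree.pattern.value)
print()
print("The 5 fully shared mutations sit on the trunk (germline edge), the 3 "
      "R1/R2-shared ones on their common branch, and the 2 private ones on "
      "the R3 branch; the score equals the mutation count because the matrix "
      "is a perfect phylogeny.")
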