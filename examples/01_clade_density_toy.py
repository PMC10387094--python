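"""Clade density on a tiny hand-built clade.

Three species: A and B are sister taxa (splitting 0.5 time units ago on a
depth-1 tree) and overlap over 2 area units; C diverged at the root and
overlaps nobody.  Clade density weighs each pairwise overlap by the shared
evolutionary history of the pair, so A and B each score 2 x 0.5 = 1 and C
scores 0.
"""

import numpy as np

from cladedensity import OverlapMatrix, align_species, clade_density, read_newick, vcv

tree = read_newick("((A:0.5,B:0.5):0.5,C:1);")
V = vcv(tree)
print("phylogenetic variance-covariance (MRCA depths):")
print(V.to_frame(), "\n")

overlap = np.diag([5.0, 4.0, 6.0])  # range sizes on the diagonal
overlap[0, 1] = overlap[1, 0] = 2.0  # A and B share 2 area units
O = OverlapMatrix(("A", "B", "C"), overlap)

O_aligned, V_aligned, _ = align_species(O, V)
table = clade_density(O_aligned, V_aligned)
print("clade density (area x time units):")
print(table.series())
print(
    "\nA and B: overlap 2.0 weighted by 0.5 shared time = 1.0 each; "
    "C is allopatric, so 0."
)
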