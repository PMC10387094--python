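"""Tip speciation rates (lambda_DR) from branch lengths.

The equal-splits measure ES sums root-to-tip branch lengths with weights
halved at every split (pendant branch first); lambda_DR = 1/ES.  On the
balanced depth-1 tree below every tip has ES = 0.5 + 0.5/2 = 0.75, so
lambda_DR = 4/3: short recent branches mean fast recent speciation.
"""

from cladedensity import dr_statistic, read_newick, restrict_rates

tree = read_newick("((A:0.5,B:0.5):0.5,(C:0.5,D:0.5):0.5);")
rates = dr_statistic(tree)
print(rates.to_frame(), "\n")

# When only some species have geographic data, subset the full-tree rates
# instead of recomputing on a pruned tree (pruning merges branches and
# biases rates downward):
subset = restrict_rates(rates, ["A", "C"])
print("subset (values unchanged from the full tree):")
print(subset.to_frame())
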