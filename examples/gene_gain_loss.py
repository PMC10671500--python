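"""Birth-death gene gain/loss reconstruction on the 14-taxon dated tree.

Fits the per-gene duplication/loss rate lambda to the packaged serpin
family sizes and reconstructs ancestral counts with per-branch +gain/-loss
labels, the standard readout of a gene-family expansion analysis.
"""

from serpinscape.fixtures import serpin_counts, species_tree
from serpinscape.gainloss import ancestral_counts, fit_lambda

tree = species_tree()
counts = serpin_counts()

lam_hat, boundary = fit_lambda(tree, [counts])
print(f"fitted lambda = {lam_hat:.5f} events/gene/My"
      + (" (boundary)" if boundary else ""))

amap = ancestral_counts(tree, counts, lam_hat)


def show(node, depth=0):
    label = node.name
    count = amap.node_counts[label]
    delta = (f" ({amap.branch_deltas[label]:+d})"
             if label in amap.branch_deltas else "")
    print("  " * depth + f"{label}: {count}{delta}")
    for child in node.children:
        show(child, depth + 1)


show(amap.tree)
# Internal labels N* carry the inferred ancestral family size; the signed
# number on each branch is the gain (+) or loss (-) relative to the parent.
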