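"""Compare two gene trees: RF distance, agreement subtree, shading.

Two trees that disagree about where taxon C sits are compared after
restriction to their common taxa; the agreement classification is what a
viewer would use to grey out the conflicting tips.
"""

from treebench import mast, parse_newick, rf_distance

gene1 = parse_newick("(((A,B),C),((D,E),X));")
gene2 = parse_newick("(((A,C),B),((D,E),Y));")

result = rf_distance(gene1, gene2)
print(f"common taxa: {result.common_taxon_count}")
print(f"Robinson-Foulds distance: {result.distance}")
# 5 common taxa; distance 2 = one split private to each tree (the A,B vs
# A,C disagreement); 0 would mean identical topologies on the shared taxa.

agreement = mast(gene1, gene2)
print(f"agreement subtree taxa: {sorted(agreement.mast_taxa)}")
for taxon, cls in sorted(agreement.classes(1).items()):
    print(f"  tree1 {taxon}: {cls.value}")
# in_consensus tips form the largest common structure; 'conflicting' tips
# (here one of B/C) and 'tree_specific' tips (X) would be shaded grey.
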