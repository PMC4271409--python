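"""MRP supertree from overlapping source trees.

Three source trees on different, overlapping taxon sets are coded as a
binary matrix (one character per clade, missing taxa '?') and analysed
with Fitch parsimony; the strict consensus of all most-parsimonious trees
is rooted on the synthetic outgroup and returned.
"""

from treebench import mrp_matrix, mrp_supertree, parse_newick, to_nexus, write_newick

sources = [
    parse_newick("((A,B),C);"),
    parse_newick("((B,C),D);"),
    parse_newick("((C,D),E);"),
]

matrix = mrp_matrix(sources)
print(f"matrix: {matrix.n_taxa} taxa x {matrix.n_characters} characters")
print(to_nexus(matrix))
# each character is one source clade: members 1, other taxa of that source
# 0, taxa absent from the source '?', plus an all-zero synthetic outgroup.

supertree = mrp_supertree(sources)
print(f"supertree: {write_newick(supertree)}")
# ((((A,B),C),D),E); -- the unique tree displaying all three sources.
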