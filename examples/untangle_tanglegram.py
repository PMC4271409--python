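"""Tip-order harmonization of a tanglegram.

Two trees with the same topology but scrambled child orders are untangled
by the alternating barycenter heuristic: crossings drop to zero and the
tip orders become identical, without ever changing a topology.
"""

from treebench import auto_swap, crossing_count, parse_newick

host = parse_newick("(((A,B),C),((D,E),F));")
parasite = parse_newick("((F,(E,D)),(C,(B,A)));")

before = crossing_count(host.leaf_labels(), parasite.leaf_labels())
t1, t2, layout = auto_swap(host, parasite)

print(f"crossings before: {before}")
print(f"crossings after:  {layout.crossings}")
print(f"tip order 1: {layout.order1}")
print(f"tip order 2: {layout.order2}")
# crossings count pairs of shared taxa in opposite relative order; 0 means
# the connectors of the tanglegram can be drawn without any crossing.
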