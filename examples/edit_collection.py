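"""Joint tree edition: reroot a whole collection on a multi-level outgroup.

Gene trees often lack the preferred outgroup taxon; a second outgroup
level supplies a fallback so every tree still gets a consistent root.
"""

from treebench import OutgroupSpec, TreeCollection, parse_newick, reroot_collection, write_newick

genes = TreeCollection("gene trees")
genes.add("g1", parse_newick("((Out1,(A,B)),(C,D));"))
genes.add("g2", parse_newick("((A,C),(B,Out2));"))  # Out1 missing: level 2 used
genes.add("g3", parse_newick("((A,B),(C,D));"))     # no outgroup at all

spec = OutgroupSpec([{"Out1"}, {"Out2"}])
result = reroot_collection(genes, spec)

for name, tree in result.collection.items:
    print(f"{name}: {write_newick(tree)}")
for name, warnings in result.warnings.items():
    print(f"{name}: warning: {'; '.join(warnings)}")
# g1 roots on Out1, g2 falls back to Out2, g3 is left unchanged with a
# warning -- per-tree best effort, never a partial-failure abort.
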