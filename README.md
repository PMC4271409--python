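# treebench

Collection-aware comparison and editing of phylogenetic trees, for anyone
who has to reconcile many gene trees against each other or against a
species tree: tree edition applied jointly to whole collections, pairwise
topological comparison, supertree summaries of overlapping trees, and a
file-backed project store with single-writer collaboration semantics.

## What it computes

**Robinson–Foulds distance.** Two trees are first restricted to their
common taxa; the distance is `|B(T1) Δ B(T2)|`, the symmetric difference
of their nontrivial unrooted bipartition sets (the full count, not half).

**Maximum agreement subtree (rooted MAST).** The largest taxon subset `S`
such that `T1|S` and `T2|S` are isomorphic as rooted trees, found by a
dynamic program over node pairs with maximum-weight bipartite matching of
child subproblems at internal/internal cells. Every leaf of each tree is
classified `in_consensus` / `conflicting` / `tree_specific`, which drives
grey shading in the SVG export.

**Tanglegram untangling.** `auto_swap` harmonizes tip orders by an
alternating barycenter heuristic (children sorted by mean rank of their
common leaves in the other tree's order). The inversion count between the
tip orders — equal to the number of line crossings with straight
connectors — never increases, and only child orders change.

**MRP supertrees.** Source trees are coded in the Baum–Ragan matrix (one
binary character per clade: members 1, other taxa of that source 0, taxa
absent from the source `?`, plus an all-zero synthetic outgroup). The
matrix is analysed under equal-weight Fitch parsimony: exhaustively
(branch and bound, returning *all* most-parsimonious topologies) up to a
configurable taxon threshold, and by seeded random-addition + NNI hill
climbing beyond it. The supertree is the strict consensus of the MP trees,
rooted on the synthetic outgroup.

**Tree edition.** Rerooting on multi-level outgroups (fallback levels for
trees missing the preferred outgroup), restriction to common taxa with
branch-length-preserving pruning, manual subtree swaps, coordinated
renaming and colouring — each available per tree or across a collection
with per-tree warning aggregation.

**Projects.** Two named collections per project, member roles, a
private/public status with guest read-only access, upload limits enforced
atomically (10,000 trees and 5,000 distinct taxa per project, 1,000 trees
per import), an append-only timeline, named backups with exact restore,
and a single-writer control token (request / accept / decline / take).

## Worked example

```python
from treebench import mast, parse_newick, rf_distance

gene1 = parse_newick("(((A,B),C),((D,E),X));")
gene2 = parse_newick("(((A,C),B),((D,E),Y));")

print(rf_distance(gene1, gene2))
# RFResult(common_taxon_count=5, distance=2)

agreement = mast(gene1, gene2)
print(sorted(agreement.mast_taxa))
# ['A', 'B', 'D', 'E']
```

The two trees share 5 taxa and disagree by one split on each side
(distance 2): they differ only in whether B or C is closer to A. The
agreement subtree keeps 4 of the 5 common taxa; C is `conflicting` and
would be shaded grey, X and Y are `tree_specific` to their trees.

More narrative scripts live in `examples/` (one per capability); each
prints the numbers it computes and says what they mean. The same
operations are available from a thin CLI:

```sh
treebench rf a.nwk b.nwk          # prints "<common taxa>\t<distance>"
treebench mrp sources.nwk -o supertree.nwk
treebench project create proj/ --name demo --admin alice
```

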