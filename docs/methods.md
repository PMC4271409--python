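# Methods

This note records the models, algorithms and design choices behind
treebench, in the spirit of a methods appendix: what each component
assumes, which knobs matter, and what the synthetic inputs used by the
test suite do and do not establish about real data.

## Tree model and Newick dialect

The universal object is a rooted, *ordered* tree: child order is
semantically significant because it defines the displayed tip order that
the swap and untangling tools manipulate. Leaf labels are unique and
non-empty; internal nodes carry an optional support value or name, and a
branch length to the parent; leaves carry a free annotation map (colours
live under the key `color`).

Newick dialect decisions: single quotes delimit labels containing
special characters (`''` escapes a quote); underscores are passed through
verbatim, never translated to spaces; an internal-node label that parses
as a number is stored as a support value, anything else as a name.
Parsing is delegated to dendropy and converted into this model; writing
is native so that floats round-trip exactly (shortest-round-trip
formatting, integers printed without a decimal point) and
`parse(write(t)) == t` holds including child order, lengths and supports.

## Restriction and rerooting

`restrict_to_taxa` returns the induced subtree: pruned leaves removed,
unary nodes suppressed with branch lengths summed (a missing length
absorbs: missing + x = missing), relative nesting untouched. This is the
standard pruning semantics and is validated by exhaustive rooted-triplet
preservation at small n.

`reroot_outgroup` scans outgroup levels outermost-first and uses the
first level with any representative; the tree is rerooted on the edge
above the MRCA of the representatives. Choices where the underlying
behaviour was genuinely open:

- the split edge's length is divided **equally** between the two new root
  children (the least informative symmetric choice); absent lengths stay
  absent;
- on every reversed edge the (length, support) pair travels with the
  edge, so supports keep describing the same unrooted bipartition;
- a non-monophyletic outgroup whose MRCA is not the root is accepted with
  a warning (gene trees are rarely clean); if its MRCA *is* the root, the
  complement's MRCA is used when the complement is a clade, otherwise the
  operation fails as "not monophyletic";
- with no representative at any level the tree is returned unchanged with
  a warning, and collection-level rerooting is always per-tree best
  effort with aggregated warnings, never a partial abort.

Rerooting provably leaves the unrooted bipartition set unchanged, and the
tests assert exactly that.

## Robinson–Foulds distance

Computed on unrooted nontrivial bipartitions after restriction to the
common taxa, reported as the full symmetric-difference count together
with the common-taxon count. Requires ≥ 4 common taxa (below that no
nontrivial split exists and the distance is undefined). Correctness is
established against two independent routes: a naive per-edge
BFS-over-adjacency oracle, and dendropy's symmetric difference.

## Rooted maximum agreement subtree

The DP is over node pairs `(u, v)`:
`M(u,v) = max( max_c M(c,v), max_d M(u,d), matching(u,v) )`, where
`matching` is a maximum-weight bipartite matching of the children of `u`
against the children of `v` (solved with `scipy.optimize.
linear_sum_assignment`), and a leaf matches iff its label occurs below
the other node. This handles multifurcations exactly. Both trees are
restricted to their common taxa first.

Tie-breaking: when several maximum agreement sets exist the DP prefers,
at every cell, the candidate whose sorted taxon tuple is
lexicographically smallest — a deterministic choice that makes results
reproducible; passing a seed instead samples ties uniformly. The
returned per-leaf classification (`in_consensus` = in the agreement set,
`tree_specific` = absent from the other tree, `conflicting` = the rest)
partitions each tree's leaf set by construction.

Exactness is checked against exhaustive subset search for ≤ 7 common
taxa; for larger trees the returned set is verified to be a true
agreement set by restriction + isomorphism.

## Tanglegram untangling

The objective is the inversion count between the two tip orders
restricted to shared taxa (identical to straight-connector crossings).
One half-step holds one tree fixed and sorts every node's children by the
mean rank of their common leaves in the fixed order; children with no
common leaves keep their previous relative order after the others; ties
on the mean break by smallest leaf name. Sides alternate until a
fixpoint or a round limit (default 10). Barycenter steps can in
principle overshoot, so each half-step is accepted only if it does not
increase the crossing count — otherwise it is reverted and iteration
stops, which makes monotonicity a guarantee rather than a tendency. For
two trees with the same unordered topology one half-step aligns the
orders exactly, so crossings always reach zero in that case.

## MRP supertrees

Coding is Baum–Ragan over **rooted** source trees: one character per
nontrivial proper clade, members 1, other taxa of the source 0, absent
taxa `?`, plus a synthetic all-zero outgroup row (`__MRP_ROOT__`) that
fixes the root of the analysis. Characters are ordered by (source tree,
clade preorder) and the matrix exports to NEXUS and relaxed PHYLIP.

Scoring is equal-weight small parsimony with `?` = {0,1}. The per-node
update is Hartigan's rule (state counts, exact for multifurcations; it
reduces to Fitch's intersection/union on binary nodes), vectorized over
characters with numpy bitmasks.

Search: up to the exhaustive threshold (default 9 taxa, including the
synthetic outgroup row when present) the search enumerates unrooted
binary topologies by stepwise leaf addition with branch-and-bound
pruning. Because the parsimony score of an induced subtree never exceeds
that of the full tree, a partial tree scoring above the current best can
be discarded with all its completions; the bound is seeded with a greedy
stepwise-addition tree. The result is exactly the set of **all**
most-parsimonious topologies (with zero characters this degenerates to
full enumeration, where every topology ties at 0). Beyond the threshold,
seeded random-addition starts (default 8) are refined by
nearest-neighbour-interchange hill climbing (first-improvement, round
limit 50) and the best-scoring trees are pooled and deduplicated by
bipartition set. The heuristic may return a subset of the MP set; it is
tested never to return a non-MP tree when the exact set is known.

Because multiple MP trees are common, the pipeline returns the strict
consensus of the MP set (clade-intersection, multifurcating where they
disagree), rooted on the synthetic outgroup and with that leaf removed —
exposing the full MP set rather than an arbitrary single tree.

### When is exact recovery possible?

A binary supertree problem has the model tree as its unique answer only
when the source trees jointly *define* it — when the model is the only
binary tree displaying every source. Split-wise coverage (every model
split witnessed with ≥ 2 taxa a side in some source) is **not**
sufficient: families satisfying it routinely admit several MP trees, and
the strict consensus then loses resolution. `definitive_subtree_sample`
therefore rejection-samples subset families until an independent
enumeration oracle (`count_displaying_trees`, stepwise addition with
restriction-isomorphism pruning, sharing no code with the parsimony
machinery) certifies uniqueness. Under that precondition the MRP pipeline
recovers the model exactly (RF = 0) in the recovery experiments; without
it, every supertree split remains compatible with the model. Roughly a
quarter of random 6×5-taxon families over a 9-taxon model are definitive,
so sampling is cheap.

## Project store

State is plain data (dataclasses) with pure-ish operations; persistence
is one directory per project: Newick per collection, `(taxon,key,value)`
annotation CSV sidecars, a JSON metadata document, backups as
subdirectories of the same shape. Decisions taken where the behaviour
was open: projects are identified by an opaque id (names are not unique
keys); the control token starts vacant and is granted to the first
requester; a declined requester may immediately re-request; the
5,000-taxon cap counts distinct taxa per project (not per collection);
the two collections are fixed in number but renameable; a member who
detaches from the shared view (sync flag) has mutating calls rejected.

Limits (10,000 trees/project, 5,000 distinct taxa/project, 1,000
trees/import) are validated before any mutation, so a rejected import
leaves the project byte-identical. The single-holder invariant is
property-tested over random event sequences, and the acceptance script
re-probes the thresholds behaviourally by binary search on
accepted/rejected imports.

## Rendering

Rectangular phylogram only: x from cumulative branch lengths (a missing
length counts as one unit), y from tip order, one `<text>` per leaf.
With an agreement result, out-of-consensus leaves and the edges of
subtrees whose leaves are *all* out of consensus are drawn in the shading
colour (default `#b8b8b8`); in-consensus leaves keep their `color`
annotation. Pairs render side by side or face to face (second tree
mirrored, labels anchored inward). Output is deterministic text, so
identical inputs give byte-identical SVG.

## Synthetic data and what the tests show

All test inputs come from `treebench.simulate`: uniformly random rooted
binary topologies by sequential random leaf attachment (every edge,
including the virtual root edge, equally likely — giving the uniform
distribution over the (2n−3)!! labelled shapes, checked by a chi-square
test at n = 4), optionally restricted to random subsets to emulate
unequal leaf sets. These fixtures exercise topology handling exhaustively
at small n but are idealized: no branch-length signal, no polytomies
beyond those created by consensus, no label noise, and taxon overlap
patterns are random rather than phylogenetically structured. Passing
tests therefore establish algorithmic correctness (agreement with
brute-force oracles, invariant preservation), not robustness to the
pathologies of real data sets.

Problem sizes in tests and in the acceptance script (tree pairs up to 16
taxa for RF, 7/12 for exact/valid MAST checks, 6-leaf trees for the
parsimony oracle, a 9-taxon model with six 5-taxon sources for supertree
recovery, 200–1,000 replicates per property) were chosen so the whole
suite runs in seconds on one core while still covering every code path
that scales; the algorithms themselves have no such limits beyond the
exponential cost of the exact searches.

## Known limitations

- Unrooted MAST is out of scope; MAST is rooted by design.
- Supertrees carry no branch lengths or supports.
- The NNI heuristic can miss MP trees (and in adversarial matrices the
  MP *score*); raise `starts` or the exhaustive threshold where exactness
  matters and the taxon count allows.
- The project store models collaboration as a state machine; it provides
  no real concurrency control beyond the token semantics.
- Only Newick input is accepted (no NEXUS/PhyloXML trees), and SVG output
  is deliberately minimal.
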