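# treeside

Side-by-side phylogenetic tree comparison as a library and CLI.

Given two trees in Newick format over the same taxa, treeside scores every
node of each tree against its *best corresponding node* (BCN) in the other
tree — the node maximizing the Jaccard similarity of the leaf sets below
them — and uses those scores to drive:

- **automatic best rooting**: reroot the second tree on the edge that
  maximizes the mean BCN score against the first;
- **branch-swap leaf ordering**: permute children (barycenter heuristic) to
  minimize discordant leaf pairs between the two displayed leaf orders;
- **viewport-driven collapsing**: estimate the deepest collapse level whose
  visible rows (leaves + triangle stubs) still fit the viewport, with path
  expansion to reveal any node of interest;
- **deterministic SVG rendering** of one tree or two mirrored trees side by
  side, node glyphs colored on a yellow-to-blue ramp by their BCN score,
  with highlight / selection / search-path overlays as CSS classes.

Leaf sets are bitset fingerprints (arbitrary-precision integers), so
similarity reduces to `&` + popcount; the optimized BCN search only visits
ancestors of shared leaves and supports lazy evaluation of just the visible
nodes. An exhaustive O(n²) oracle (`bcn_oracle`) backs every optimized path
in the tests. Visualization state (collapsed/highlighted nodes, viewport)
round-trips through an NHX-style extended Newick dialect that plain parsers
read unchanged.

## CLI

```sh
# single tree -> SVG; auto-collapse, search-path coloring, rerooting
treeside view tree.nwk --out tree.svg --search SOME_LEAF --collapse-depth auto

# two trees side by side; prints the aggregate BCN score (6 decimals)
treeside compare a.nwk b.nwk --best-root --optimize-order \
    --out compare.svg --out-newick annotated.nwk --highlight SOME_LEAF
```

Exit codes: 0 success, 2 input error (unreadable file, malformed Newick),
3 validation error (duplicate labels, mismatched leaf sets). A `--config`
file of `key=value` lines supplies defaults; flags take precedence.

## Library sketch

```python
from treeside import (parse_newick, compare, best_rooting,
                      optimize_leaf_order, VizState, RenderSpec,
                      render_compare)

t1 = parse_newick(open("a.nwk").read())
t2 = parse_newick(open("b.nwk").read())
t2 = optimize_leaf_order(t1, best_rooting(t1, t2))
cmp = compare(t1, t2)            # scores, BCN maps, aggregate in [0, 1]
svg = render_compare(t1, t2, cmp, VizState(), VizState(), RenderSpec())
```

Modules: `newick_io` (plain + extended Newick), `tree_model` (nodes,
fingerprints, rerooting, splits), `comparison` (similarity, BCN fast +
oracle), `layout_ops` (rooting search, leaf ordering, collapsing,
search/highlight), `render` (SVG), `fixtures` (seeded random trees, NNI /
reroot / shuffle perturbations), `cli`.

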