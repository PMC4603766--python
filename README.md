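# netrec — duplication–loss reconciliation of gene trees with species networks

When species hybridize, their phylogeny is not a tree but a rooted
phylogenetic *network*: a binary DAG whose extra, hybridization nodes
(indegree 2, outdegree 1) merge two parental lineages.  Classic
duplication–loss (DL) reconciliation — explaining the incongruence between a
gene tree *G* and a species phylogeny by gene duplications (cost δ each) and
gene losses (cost λ each) — must then be rethought.  `netrec` implements two
variants for a binary gene tree against a binary rooted species network *N*,
for phylogeneticists studying gene-family evolution under reticulation:

1. **Best switching.**  A *switching* of *N* keeps one incoming edge per
   hybridization node (plus a closure rule) and thereby selects one of the
   trees displayed by the network; losses are counted only at speciation
   nodes untouched by switched-off edges.  The problem is to find the
   switching *S* minimizing `cost(G, S) = δ·d + λ·l` of the (unique optimal)
   LCA reconciliation.  Although a network with *h* hybridization nodes has
   up to `2^h` switchings, the cost decomposes exactly over the biconnected
   components of *N*, so the search enumerates each component's `≤ 2^k`
   switchings independently (*k* = network level, the per-component
   hybridization maximum) — fixed-parameter tractable in the level.

2. **Minimum reconciliation on the network.**  Gene-tree nodes map to
   arbitrary network nodes; a speciation image needs two separated paths to
   the children's images, and losses are counted on shortest paths (a path's
   length is its number of speciation-or-root nodes, top endpoint included,
   bottom excluded; hybridization nodes are free).  A post-order dynamic
   program keeps, per gene node *u*, the candidate set C(u) of
   (image, minimal cost) pairs; speciation candidates range over the
   *minimal meeting set* — the lowest non-dominated nodes with separated
   paths to both child images — and candidate sets provably stay within
   h + 2 entries, giving an `O(h²·|G|·|N|)` algorithm with backtracking to
   an explicit event-annotated reconciliation.

Both solvers ship with independent brute-force oracles (global switching
enumeration; full-space reconciliation search) and a seeded generator of
random networks and simulated gene families with known event histories.

## Worked example

The "diamond" network — root `r` with children `a`, `b`; a hybridization
node below both, leading to `Z`; `a` also carries `X` and `b` carries `Y` —
is written in extended Newick as `((X,(Z)#H1),(#H1,Y));` (the tag `#H1`
appears once with the hybrid's subtree, once as its second parent).  For the
gene family `((X,Z),Y);`:

```sh
$ netrec best-switching --gene fam.nwk --network diamond.enwk --format tsv
best switching cost=0.0 d=0 l=0 (h=1 level=1 component_evaluations=2)
# problem       best-switching
# total_cost    0.0
# displayed_tree        ((X,Z),Y);
...
```

Keeping the hybrid edge from `a` displays the tree `((X,Z),Y)` — exactly the
gene tree — so the best switching explains the family with zero duplications
and zero losses (a gene tree displayed by the network always costs 0).
Against the *whole* network the same family costs λ = 1:

```sh
$ netrec reconcile --gene fam.nwk --network diamond.enwk --format tsv
minimum reconciliation cost=1.0 d=0 l=1
```

The cherry `(X,Z)` speciates at `a` free of charge (the path to `Z` passes
only the uncounted hybridization node), but the root's speciation at `r`
pays one loss at `b` on the way to `Y` — in the whole-network model there is
no switching to declare `b`'s non-contribution event-free.  The per-row TSV
lists each gene node's image, event (`S`/`D`/`C`) and losses.

`netrec generate --leaves 5 --hybridizations 2 --seed 42 --out-prefix fix`
writes a random network (`fix.enwk`), a simulated gene tree (`fix.nwk`) and
a JSON manifest with the true switching and event counts of the surviving
history.

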