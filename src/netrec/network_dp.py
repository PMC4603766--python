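"""Minimum duplication-loss reconciliation against the whole network.

A post-order dynamic program computes, for every gene-tree node ``u``, the
candidate set ``C(u)`` of pairs ``(x, c)``: ``x`` a network node and ``c``
the minimum cost of reconciling the subtree at ``u`` while mapping ``u`` to
``x``.  Leaves seed their species leaf at cost zero.  For an internal node,
every pair of child candidates ``(y, c1)`` and ``(z, c2)`` contributes

* speciation candidates at every node of the minimal meeting set of ``y``
  and ``z`` (lowest nodes with two separated paths to both), paying the
  cheapest pairing of loss distances through the node's two children, and
* a duplication candidate at the higher of ``y, z`` when they are
  comparable, paying the duplication cost plus the loss distance between
  them.

Merging keeps one minimum-cost pair per node.  In a most parsimonious
reconciliation every image lies in the meeting set of the relevant species
leaves, whose size is bounded by ``h + 2`` for ``h`` hybridization nodes, so
candidate sets stay small and the whole program runs in ``O(h^2 |G| |N|)``.

The minimal meeting set is computed by two upward traversals from ``y`` and
``z``: every node strictly above both is labelled with the lowest node that
all of its paths to ``y`` and ``z`` must pass; a node whose relevant
children disagree on that label is itself a lowest non-dominated meeting
node.  Nodes are processed in (reverse) topological order so that labels of
children are always available, which is what breadth-first layering alone
would not guarantee on a DAG.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import (
    CONTEMP_EVENT,
    DUP_EVENT,
    INF,
    SPEC_EVENT,
    CostParams,
    GeneTree,
    Network,
    NetworkError,
    NormalizedGeneTree,
    Reconciliation,
    validate_reconciliation,
)


@dataclass
class MinLabeling:
    """Output of the upward label propagation for one node pair."""

    min_set: set[int]
    dist_to_y: dict[int, float]
    dist_to_z: dict[int, float]
    label: dict[int, int | None]


def compute_min(network: Network, y: int, z: int) -> MinLabeling:
    """Minimal meeting set of ``y`` and ``z`` with distance tables.

    Matches the brute-force definition: meeting nodes not dominated by
    another meeting node lying on all their paths to ``y`` and ``z``.
    """
    network._check_node(y, z)
    anc_y = {v for v in network.graph if network.leq(y, v)}
    anc_z = {v for v in network.graph if network.leq(z, v)}
    label: dict[int, int | None] = {}
    min_set: set[int] = set()
    # Children before parents.
    for v in reversed(network.topo_order):
        if v not in anc_y and v not in anc_z:
            continue
        if v == y or v == z or v not in anc_y or v not in anc_z:
            label[v] = None
            continue
        relevant = [
            c for c in network.children(v) if c in anc_y or c in anc_z
        ]
        if len(relevant) == 1:
            label[v] = label.get(relevant[0])
        else:
            l1, l2 = (label.get(c) for c in relevant)
            if l1 == l2 and l1 is not None:
                label[v] = l1
            else:
                label[v] = v
                min_set.add(v)
    dist_to_y = {v: network.dist(v, y) for v in anc_y}
    dist_to_z = {v: network.dist(v, z) for v in anc_z}
    return MinLabeling(
        min_set=min_set, dist_to_y=dist_to_y, dist_to_z=dist_to_z, label=label
    )


@dataclass
class NetworkDPResult:
    """Candidate tables and minimum cost of the network reconciliation.

    ``cost`` refers to the input gene tree; ``cost_normalized`` to its
    single-species-collapsed form (they differ by one duplication cost per
    collapsed internal node).  ``tables`` maps each node of the normalized
    tree to its candidate set ``{x: cost}``.
    """

    gene_tree: GeneTree
    network: Network
    costs: CostParams
    normalized: NormalizedGeneTree
    tables: dict[int, dict[int, float]]
    back: dict[int, dict[int, tuple]]
    cost: float
    cost_normalized: float
    max_candidate_size: int


def reconcile_network(
    gene_tree: GeneTree, network: Network, costs: CostParams | None = None
) -> NetworkDPResult:
    """Compute the minimum reconciliation cost between a gene tree and a
    network, with full candidate tables for backtracking."""
    costs = costs or CostParams()
    norm = gene_tree.normalize()
    tree = norm.tree
    for lab in tree.species:
        if lab not in network.label_to_leaf:
            raise NetworkError(f"gene leaf label {lab!r} absent from network")
    tables: dict[int, dict[int, float]] = {}
    back: dict[int, dict[int, tuple]] = {}
    min_cache: dict[tuple[int, int], MinLabeling] = {}

    def minset(y: int, z: int) -> MinLabeling:
        key = (y, z) if y <= z else (z, y)
        if key not in min_cache:
            min_cache[key] = compute_min(network, *key)
        return min_cache[key]

    max_size = 0
    for u in tree.postorder():
        if tree.is_leaf(u):
            x = network.label_to_leaf[tree.leaf_label[u]]
            tables[u] = {x: 0.0}
            back[u] = {x: (CONTEMP_EVENT,)}
        else:
            u1, u2 = tree.children[u]
            cu: dict[int, float] = {}
            bu: dict[int, tuple] = {}

            def offer(x: int, c: float, tag: tuple) -> None:
                if x not in cu or c < cu[x]:
                    cu[x] = c
                    bu[x] = tag

            for y, c1 in sorted(tables[u1].items()):
                for z, c2 in sorted(tables[u2].items()):
                    ml = minset(y, z)
                    for x in sorted(ml.min_set):
                        x1, x2 = network.children(x)
                        loss = min(
                            network.dist(x1, y) + network.dist(x2, z),
                            network.dist(x1, z) + network.dist(x2, y),
                        )
                        if loss == INF:
                            continue
                        offer(
                            x,
                            c1 + c2 + costs.loss * loss,
                            (SPEC_EVENT, y, z),
                        )
                    if network.leq(y, z):
                        offer(
                            z,
                            costs.dup + costs.loss * network.dist(z, y) + c1 + c2,
                            (DUP_EVENT, y, z),
                        )
                    elif network.leq(z, y):
                        offer(
                            y,
                            costs.dup + costs.loss * network.dist(y, z) + c1 + c2,
                            (DUP_EVENT, y, z),
                        )
            if not cu:
                raise NetworkError(
                    f"empty candidate set at gene node {u}: internal error"
                )
            tables[u] = cu
            back[u] = bu
        max_size = max(max_size, len(tables[u]))
    cost_norm = min(tables[tree.root].values())
    return NetworkDPResult(
        gene_tree=gene_tree,
        network=network,
        costs=costs,
        normalized=norm,
        tables=tables,
        back=back,
        cost=cost_norm + costs.dup * norm.n_collapsed_duplications,
        cost_normalized=cost_norm,
        max_candidate_size=max_size,
    )


def backtrack(result: NetworkDPResult) -> Reconciliation:
    """Extract an explicit minimum-cost reconciliation of the input tree.

    Starts from the cheapest root candidate (smallest node id on ties),
    follows the stored predecessor tuples, re-expands collapsed
    single-species subtrees as duplications at the image leaf, validates the
    result and checks that its recomputed cost matches the table minimum.
    """
    tree = result.normalized.tree
    tables, back = result.tables, result.back
    root_items = sorted(tables[tree.root].items(), key=lambda kv: (kv[1], kv[0]))
    x0, best = root_items[0]
    alpha_r: dict[int, int] = {}
    alpha_e: dict[int, str] = {}
    stack = [(tree.root, x0)]
    while stack:
        u, x = stack.pop()
        tag = back[u][x]
        alpha_r[u] = x
        alpha_e[u] = tag[0]
        if tag[0] != CONTEMP_EVENT:
            _, y, z = tag
            u1, u2 = tree.children[u]
            stack.append((u1, y))
            stack.append((u2, z))
    full_r, full_e = result.normalized.expand(alpha_r, alpha_e)
    report = validate_reconciliation(
        result.gene_tree, result.network, full_r, full_e, result.costs
    )
    if not report.valid:
        raise NetworkError(f"backtracked reconciliation invalid: {report.violation}")
    if abs(report.cost - result.cost) > 1e-9:
        raise NetworkError(
            f"backtracked cost {report.cost} != table minimum {result.cost}"
        )
    return Reconciliation(
        alpha_r=full_r,
        alpha_e=full_e,
        losses=report.losses,
        d=report.d,
        l=report.l,
        cost=report.cost,
    )
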