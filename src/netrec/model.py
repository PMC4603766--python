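"""Core data model: species networks, gene trees, switchings, reconciliations.

A *species network* is a rooted binary directed acyclic graph: the root has
indegree 0 and outdegree 2, speciation nodes have indegree 1 and outdegree 2,
hybridization (reticulation) nodes have indegree 2 and outdegree 1, and leaves
(outdegree 0) are bijectively labelled by species names.  A *gene tree* is a
rooted binary tree whose leaves are labelled by species names, possibly with
repeats.  A *switching* selects one incoming edge per hybridization node and
propagates the induced switch-offs, turning the network into a displayed tree.

A *reconciliation* maps every gene-tree node ``u`` to a pair
``(alpha_r(u), alpha_e(u))`` where ``alpha_r(u)`` is a network node and
``alpha_e(u)`` is an event: speciation ``"S"``, duplication ``"D"``, or the
contemporary event ``"C"`` tying a gene leaf to the species leaf of the same
label.  Losses are counted on shortest paths: the distance ``dist(x, y)``
between comparable nodes is the minimum, over directed paths from ``x`` down
to ``y``, of the number of speciation-or-root nodes ``z`` with
``y < z <= x`` on the path; hybridization nodes are never counted.  On a
switching the path is unique and only nodes untouched by switched-off edges
(the set ``V_on``) contribute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping, Sequence

import networkx as nx

#: Saturating infinity used for distances between incomparable nodes.
INF = math.inf

ROOT = "root"
SPECIATION = "speciation"
HYBRIDIZATION = "hybridization"
LEAF = "leaf"

SPEC_EVENT = "S"
DUP_EVENT = "D"
CONTEMP_EVENT = "C"


class NetworkError(ValueError):
    """Raised when a candidate digraph is not a valid species network."""


class GeneTreeError(ValueError):
    """Raised when a candidate tree is not a valid binary gene tree."""


class ReconciliationError(ValueError):
    """Raised when a reconciliation query refers to unmapped nodes."""


@dataclass(frozen=True)
class CostParams:
    """Positive event costs: ``dup`` for a duplication, ``loss`` per loss."""

    dup: float = 1.0
    loss: float = 1.0

    def __post_init__(self) -> None:
        if not (self.dup > 0):
            raise ValueError(f"duplication cost must be positive, got {self.dup}")
        if not (self.loss > 0):
            raise ValueError(f"loss cost must be positive, got {self.loss}")


class Network:
    """A validated rooted binary phylogenetic species network.

    Nodes are stable integer ids.  Use :func:`validate_network` to build one
    from an arbitrary labelled digraph.
    """

    def __init__(self, graph: nx.DiGraph, leaf_label: Mapping[int, str]):
        self.graph = graph
        self.leaf_label = dict(leaf_label)
        self._classify()
        self._desc: dict[int, frozenset[int]] = {}
        self._dist_memo: dict[tuple[int, int], float] = {}
        order = list(nx.topological_sort(graph))
        self.topo_order = order  # parents before children
        self.topo_rank = {v: i for i, v in enumerate(order)}
        for v in reversed(order):
            below = {v}
            for c in graph.successors(v):
                below |= self._desc[c]
            self._desc[v] = frozenset(below)
        self.label_to_leaf = {lab: v for v, lab in self.leaf_label.items()}

    # -- construction -----------------------------------------------------

    def _classify(self) -> None:
        g = self.graph
        self.kind: dict[int, str] = {}
        roots = [v for v in g if g.in_degree(v) == 0]
        if len(roots) != 1:
            raise NetworkError(f"expected exactly one root, found {sorted(roots)}")
        self.root = roots[0]
        for v in g:
            ind, outd = g.in_degree(v), g.out_degree(v)
            if v == self.root:
                if outd != 2:
                    raise NetworkError(f"root {v} has outdegree {outd}, non-binary")
                self.kind[v] = ROOT
            elif outd == 0:
                if ind != 1:
                    raise NetworkError(f"leaf {v} has indegree {ind}")
                self.kind[v] = LEAF
            elif (ind, outd) == (1, 2):
                self.kind[v] = SPECIATION
            elif (ind, outd) == (2, 1):
                self.kind[v] = HYBRIDIZATION
            else:
                raise NetworkError(
                    f"node {v} has degrees (in={ind}, out={outd}), non-binary"
                )
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise NetworkError(f"graph contains a cycle through {cycle[0][0]}")
        leaves = {v for v, k in self.kind.items() if k == LEAF}
        if set(self.leaf_label) != leaves:
            missing = leaves - set(self.leaf_label)
            extra = set(self.leaf_label) - leaves
            raise NetworkError(
                f"leaf labelling mismatch: unlabelled {sorted(missing)}, "
                f"labels on non-leaves {sorted(extra)}"
            )
        seen: dict[str, int] = {}
        for v in sorted(leaves):
            lab = self.leaf_label[v]
            if lab in seen:
                raise NetworkError(
                    f"duplicate leaf label {lab!r} on nodes {seen[lab]} and {v}"
                )
            seen[lab] = v

    # -- basic accessors ---------------------------------------------------

    @property
    def nodes(self) -> list[int]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[int, int]]:
        return sorted(self.graph.edges)

    @property
    def leaves(self) -> list[int]:
        return sorted(v for v, k in self.kind.items() if k == LEAF)

    @property
    def species(self) -> set[str]:
        return set(self.leaf_label.values())

    @property
    def size(self) -> int:
        return self.graph.number_of_nodes() + self.graph.number_of_edges()

    @cached_property
    def hybridization_nodes(self) -> list[int]:
        return sorted(v for v, k in self.kind.items() if k == HYBRIDIZATION)

    @property
    def h(self) -> int:
        return len(self.hybridization_nodes)

    @cached_property
    def level(self) -> int:
        """Maximum number of hybridization nodes per biconnected component."""
        und = self.graph.to_undirected()
        best = 0
        for comp in nx.biconnected_components(und):
            if len(comp) < 3:
                continue
            k = sum(
                1
                for v in comp
                if self.kind[v] == HYBRIDIZATION
                and all(p in comp for p in self.graph.predecessors(v))
            )
            best = max(best, k)
        return best

    def children(self, v: int) -> list[int]:
        return sorted(self.graph.successors(v))

    def parents(self, v: int) -> list[int]:
        return sorted(self.graph.predecessors(v))

    def parent(self, v: int) -> int:
        """The unique parent of a non-hybridization, non-root node."""
        ps = self.parents(v)
        if len(ps) != 1:
            raise NetworkError(f"node {v} does not have a unique parent: {ps}")
        return ps[0]

    def is_counted(self, v: int) -> bool:
        """Whether ``v`` contributes to path lengths (speciation or root)."""
        return self.kind[v] in (ROOT, SPECIATION)

    def _check_node(self, *vs: int) -> None:
        for v in vs:
            if v not in self.graph:
                raise NetworkError(f"unknown node id {v}")

    # -- order, distance, meeting sets ------------------------------------

    def leq(self, x: int, y: int) -> bool:
        """True iff ``x <= y``: some directed path from ``y`` reaches ``x``."""
        self._check_node(x, y)
        return x in self._desc[y]

    def dist(self, x: int, y: int) -> float:
        """Shortest-path loss distance from ``x`` down to ``y``.

        Counts speciation-or-root nodes ``z`` with ``y < z <= x`` along the
        cheapest directed path; ``INF`` when ``y`` is not below ``x``.
        """
        self._check_node(x, y)
        if not self.leq(y, x):
            return INF
        key = (x, y)
        memo = self._dist_memo
        if key in memo:
            return memo[key]
        # Iterative DP over ancestors of y, children before parents.
        anc = [v for v in self.topo_order if y in self._desc[v]]
        for v in reversed(anc):
            if (v, y) in memo:
                continue
            if v == y:
                memo[(v, y)] = 0
                continue
            w = 1 if self.is_counted(v) else 0
            memo[(v, y)] = w + min(
                memo[(c, y)] for c in self.children(v) if y in self._desc[c]
            )
        return memo[key]

    def meeting_set(self, x: int, y: int) -> set[int]:
        """All nodes with two separated paths to ``x`` and ``y``.

        A node ``z`` with children ``c1 != c2`` qualifies when ``x`` is
        reachable through one child and ``y`` through the other.  On a tree
        with ``x, y`` incomparable this is exactly ``{LCA(x, y)}``.
        """
        self._check_node(x, y)
        out = set()
        for z in self.graph:
            cs = self.children(z)
            if len(cs) != 2:
                continue
            c1, c2 = cs
            if (self.leq(x, c1) and self.leq(y, c2)) or (
                self.leq(x, c2) and self.leq(y, c1)
            ):
                out.add(z)
        return out

    def _reaches_avoiding(self, src: int, dst: int, avoid: int) -> bool:
        if src == avoid:
            return False
        stack, seen = [src], {src}
        while stack:
            v = stack.pop()
            if v == dst:
                return True
            for c in self.graph.successors(v):
                if c != avoid and c not in seen and dst in self._desc[c]:
                    seen.add(c)
                    stack.append(c)
        return False

    def dominates(self, d: int, z: int, x: int, y: int) -> bool:
        """True iff every path from ``z`` to ``x`` and to ``y`` passes ``d``."""
        if d == z:
            return False
        return not self._reaches_avoiding(z, x, d) and not self._reaches_avoiding(
            z, y, d
        )

    def min_meeting_set(self, x: int, y: int) -> set[int]:
        """Lowest non-dominated meeting nodes of ``x`` and ``y``.

        A meeting node ``z`` is discarded when another meeting node ``d``
        lies on every path from ``z`` to ``x`` and on every path from ``z``
        to ``y``.  These are the candidate speciation placements for a most
        parsimonious reconciliation.
        """
        m = self.meeting_set(x, y)
        return {
            z for z in m if not any(self.dominates(d, z, x, y) for d in m if d != z)
        }

    def meeting_set_leaves(self, labels_or_leaves: Iterable[int]) -> set[int]:
        """Meeting set of a set of leaves.

        For a single leaf, the leaf itself.  Otherwise, all nodes above every
        leaf of the set having two separated paths to two distinct leaves of
        the set.  Its size is bounded by ``h + 2`` where ``h`` is the number
        of hybridization nodes.
        """
        L = sorted(set(labels_or_leaves))
        if not L:
            raise NetworkError("meeting_set_leaves requires a non-empty leaf set")
        for v in L:
            self._check_node(v)
            if self.kind[v] != LEAF:
                raise NetworkError(f"node {v} is not a leaf")
        if len(L) == 1:
            return set(L)
        Lset = set(L)
        out = set()
        for m in self.graph:
            cs = self.children(m)
            if len(cs) != 2:
                continue
            if not all(self.leq(l, m) for l in L):
                continue
            a = Lset & self._desc[cs[0]]
            b = Lset & self._desc[cs[1]]
            if a and b and not (len(a) == 1 and a == b):
                out.add(m)
        return out


def validate_network(
    edges: Iterable[tuple[int, int]], leaf_label: Mapping[int, str]
) -> Network:
    """Build and validate a :class:`Network` from an edge list and leaf labels.

    Raises :class:`NetworkError` naming the offending node on multiple roots,
    non-binary degrees, cycles, or duplicate leaf labels.
    """
    g = nx.DiGraph()
    g.add_edges_from(edges)
    if g.number_of_nodes() == 0:
        raise NetworkError("empty network")
    return Network(g, leaf_label)


class GeneTree:
    """A rooted binary gene tree with species-labelled leaves.

    A single-node tree (one leaf) is allowed; every internal node must have
    exactly two children.  Node ids are stable integers in input order.
    """

    def __init__(
        self,
        children: Mapping[int, Sequence[int]],
        leaf_label: Mapping[int, str],
        root: int,
    ):
        self.children = {u: tuple(cs) for u, cs in children.items()}
        self.leaf_label = dict(leaf_label)
        self.root = root
        self.parent: dict[int, int] = {}
        for u, cs in self.children.items():
            if len(cs) != 2:
                raise GeneTreeError(f"internal node {u} has {len(cs)} children")
            for c in cs:
                if c in self.parent:
                    raise GeneTreeError(f"node {c} has two parents")
                self.parent[c] = u
        all_nodes = set(self.children) | set(self.leaf_label)
        for u in all_nodes:
            if u != root and u not in self.parent:
                raise GeneTreeError(f"node {u} is disconnected from the root")
        if set(self.children) & set(self.leaf_label):
            bad = sorted(set(self.children) & set(self.leaf_label))
            raise GeneTreeError(f"nodes {bad} are both internal and labelled leaves")
        self.nodes = sorted(all_nodes)

    @property
    def leaves(self) -> list[int]:
        return sorted(self.leaf_label)

    @property
    def internal(self) -> list[int]:
        return sorted(self.children)

    @property
    def species(self) -> set[str]:
        return set(self.leaf_label.values())

    def is_leaf(self, u: int) -> bool:
        return u in self.leaf_label

    def postorder(self) -> list[int]:
        out: list[int] = []
        stack = [(self.root, False)]
        while stack:
            u, done = stack.pop()
            if done or self.is_leaf(u):
                out.append(u)
            else:
                stack.append((u, True))
                for c in reversed(self.children[u]):
                    stack.append((c, False))
        return out

    @cached_property
    def labels_below(self) -> dict[int, frozenset[str]]:
        out: dict[int, frozenset[str]] = {}
        for u in self.postorder():
            if self.is_leaf(u):
                out[u] = frozenset([self.leaf_label[u]])
            else:
                a, b = self.children[u]
                out[u] = out[a] | out[b]
        return out

    def subtree_nodes(self, u: int) -> list[int]:
        out, stack = [], [u]
        while stack:
            v = stack.pop()
            out.append(v)
            if not self.is_leaf(v):
                stack.extend(self.children[v])
        return sorted(out)

    def normalize(self) -> "NormalizedGeneTree":
        """Collapse maximal single-species subtrees into leaves.

        Internal nodes whose subtree carries a single species label are
        necessarily duplications mapped to that species' leaf in any
        minimum-cost reconciliation onto a tree or switching; collapsing them
        first and re-expanding afterwards keeps the algorithms on trees where
        every internal node separates at least two species.
        """
        new_children: dict[int, tuple[int, ...]] = {}
        new_labels: dict[int, str] = {}
        new_to_orig: dict[int, int] = {}
        collapsed_internal: dict[int, list[int]] = {}
        collapsed_leaves: dict[int, list[int]] = {}
        counter = [0]

        def fresh() -> int:
            counter[0] += 1
            return counter[0] - 1

        def build(u: int) -> int:
            nid = fresh()
            new_to_orig[nid] = u
            if self.is_leaf(u):
                new_labels[nid] = self.leaf_label[u]
            elif len(self.labels_below[u]) == 1:
                (lab,) = self.labels_below[u]
                new_labels[nid] = lab
                subtree = self.subtree_nodes(u)
                collapsed_internal[nid] = [v for v in subtree if not self.is_leaf(v)]
                collapsed_leaves[nid] = [v for v in subtree if self.is_leaf(v)]
            else:
                kids = tuple(build(c) for c in self.children[u])
                new_children[nid] = kids
            return nid

        root = build(self.root)
        tree = GeneTree(new_children, new_labels, root)
        return NormalizedGeneTree(
            original=self,
            tree=tree,
            new_to_orig=new_to_orig,
            collapsed_internal=collapsed_internal,
            collapsed_leaves=collapsed_leaves,
        )


@dataclass
class NormalizedGeneTree:
    """A gene tree with single-species subtrees collapsed, plus undo data."""

    original: GeneTree
    tree: GeneTree
    new_to_orig: dict[int, int]
    collapsed_internal: dict[int, list[int]]
    collapsed_leaves: dict[int, list[int]]

    @property
    def n_collapsed_duplications(self) -> int:
        return sum(len(v) for v in self.collapsed_internal.values())

    def expand(
        self, alpha_r: Mapping[int, int], alpha_e: Mapping[int, str]
    ) -> tuple[dict[int, int], dict[int, str]]:
        """Lift a reconciliation of the collapsed tree back to the original.

        Collapsed internal nodes become duplications mapped to the image leaf
        (zero losses each); collapsed leaves keep their contemporary event.
        """
        out_r: dict[int, int] = {}
        out_e: dict[int, str] = {}
        for nid, orig in self.new_to_orig.items():
            out_r[orig] = alpha_r[nid]
            out_e[orig] = alpha_e[nid]
        for nid, internals in self.collapsed_internal.items():
            img = alpha_r[nid]
            for v in internals:
                out_r[v] = img
                out_e[v] = DUP_EVENT
            for v in self.collapsed_leaves[nid]:
                out_r[v] = img
                out_e[v] = CONTEMP_EVENT
        return out_r, out_e


class Switching:
    """An on/off edge assignment of a network satisfying the switching rules.

    One incoming edge per hybridization node is switched on; the closure rule
    then switches off every on edge whose (internal) target has only
    switched-off outgoing edges.  Restricted to on edges, the part reachable
    from the root is a tree containing every leaf.  ``V_on`` is the set of
    nodes not incident to any off edge.
    """

    def __init__(
        self,
        network: Network,
        off_edges: Iterable[tuple[int, int]],
        choices: Mapping[int, int] | None = None,
    ):
        self.network = network
        #: Chosen on-parent per hybridization node (the pre-closure choice;
        #: the chosen edge may still be switched off by the closure).
        self.choices = dict(choices or {})
        self.off_edges = frozenset(off_edges)
        all_edges = set(network.graph.edges)
        if not self.off_edges <= all_edges:
            raise NetworkError("off edges not in the network")
        self.on_edges = frozenset(all_edges - self.off_edges)
        touched = {v for e in self.off_edges for v in e}
        self.v_on = frozenset(set(network.graph.nodes) - touched)
        # Tree structure over on edges, reachable from the root.
        self.on_parent: dict[int, int] = {}
        self.depth: dict[int, int] = {network.root: 0}
        order = [network.root]
        for v in network.topo_order:
            if v not in self.depth:
                continue
            for c in network.graph.successors(v):
                if (v, c) in self.on_edges and c not in self.depth:
                    self.on_parent[c] = v
                    self.depth[c] = self.depth[v] + 1
                    order.append(c)
        self.reachable = frozenset(self.depth)
        self._on_desc: dict[int, frozenset[int]] = {}
        for v in reversed(order):
            below = {v}
            for c in self.children_on(v):
                below |= self._on_desc[c]
            self._on_desc[v] = frozenset(below)

    @classmethod
    def from_choices(
        cls, network: Network, choices: Mapping[int, int]
    ) -> "Switching":
        """Build a switching from a chosen on-parent per hybridization node.

        Unchosen hybridization in-edges are switched off, then the closure
        is applied: any on edge whose internal target has all outgoing edges
        off is also switched off, iterated to a fixed point.
        """
        g = network.graph
        off: set[tuple[int, int]] = set()
        for hyb in network.hybridization_nodes:
            if hyb not in choices:
                raise NetworkError(f"no incoming-edge choice for hybridization {hyb}")
            keep = choices[hyb]
            parents = network.parents(hyb)
            if keep not in parents:
                raise NetworkError(f"{keep} is not a parent of hybridization {hyb}")
            for p in parents:
                if p != keep:
                    off.add((p, hyb))
        changed = True
        while changed:
            changed = False
            for v in g:
                if g.out_degree(v) == 0:
                    continue
                outs = list(g.successors(v))
                if all((v, c) in off for c in outs):
                    for p in g.predecessors(v):
                        if (p, v) not in off:
                            off.add((p, v))
                            changed = True
        return cls(network, off, choices)

    @classmethod
    def all_on(cls, network: Network) -> "Switching":
        """The identity switching of a tree (no hybridization nodes)."""
        if network.h:
            raise NetworkError("all_on switching requires a tree")
        return cls(network, ())

    # -- tree order over on edges ------------------------------------------

    def _check(self, *vs: int) -> None:
        for v in vs:
            if v not in self.network.graph:
                raise NetworkError(f"unknown node id {v}")
            if v not in self.reachable:
                raise NetworkError(f"node {v} is not reachable on switched-on edges")

    def children_on(self, v: int) -> list[int]:
        return sorted(
            c
            for c in self.network.graph.successors(v)
            if (v, c) in self.on_edges and c in self.reachable
        )

    def leq(self, x: int, y: int) -> bool:
        """True iff the unique on-path from ``y`` reaches ``x``."""
        self._check(x, y)
        while self.depth[x] > self.depth[y]:
            x = self.on_parent[x]
        return x == y

    def lca(self, x: int, y: int) -> int:
        self._check(x, y)
        while self.depth[x] > self.depth[y]:
            x = self.on_parent[x]
        while self.depth[y] > self.depth[x]:
            y = self.on_parent[y]
        while x != y:
            x = self.on_parent[x]
            y = self.on_parent[y]
        return x

    def dist(self, x: int, y: int) -> float:
        """Loss distance along the unique on-path from ``x`` down to ``y``.

        Counts speciation-or-root nodes in ``V_on`` strictly above ``y`` and
        below-or-equal ``x``; ``INF`` when ``y`` is not below ``x``.
        """
        self._check(x, y)
        count = 0
        v = y
        while v != x:
            if v not in self.on_parent:
                return INF
            v = self.on_parent[v]
            if v in self.v_on and self.network.is_counted(v):
                count += 1
        return count

    def meeting_set(self, x: int, y: int) -> set[int]:
        """Separated-path meeting nodes using only switched-on edges."""
        self._check(x, y)
        out = set()
        for z in self.reachable:
            cs = self.children_on(z)
            if len(cs) != 2:
                continue
            c1, c2 = cs
            d1, d2 = self._on_desc[c1], self._on_desc[c2]
            if (x in d1 and y in d2) or (x in d2 and y in d1):
                out.add(z)
        return out

    def leaf_of_label(self, label: str) -> int:
        return self.network.label_to_leaf[label]

    def sort_key(self) -> tuple:
        """Deterministic identity of the switching: sorted on-edge set."""
        return tuple(sorted(self.on_edges))


@dataclass
class Reconciliation:
    """An event-annotated reconciliation with per-node loss counts."""

    alpha_r: dict[int, int]
    alpha_e: dict[int, str]
    losses: dict[int, float]
    d: int
    l: float
    cost: float

    def rows(self) -> list[tuple[int, int, str, float]]:
        return [
            (u, self.alpha_r[u], self.alpha_e[u], self.losses.get(u, 0))
            for u in sorted(self.alpha_r)
        ]


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_reconciliation`."""

    valid: bool
    violation: str | None
    d: int = 0
    l: float = 0.0
    cost: float = 0.0
    losses: dict[int, float] = field(default_factory=dict)


def _target_ops(target):
    """Uniform (leq, dist, meeting_set, kind) views over Network/Switching."""
    if isinstance(target, Switching):
        net = target.network
        return target.leq, target.dist, target.meeting_set, net
    return target.leq, target.dist, target.meeting_set, target


def event_losses(
    target, alpha_r: Mapping[int, int], u: int, u1: int, u2: int, event: str
) -> float:
    """Loss count of internal gene node ``u`` under the stated event.

    Speciation: best pairing of the two children of the image with the two
    child images, by loss distance.  Duplication: summed distance from the
    image to both child images.
    """
    leq, dist, _, net = _target_ops(target)
    x = alpha_r[u]
    a1, a2 = alpha_r[u1], alpha_r[u2]
    if event == DUP_EVENT:
        return dist(x, a1) + dist(x, a2)
    cs = net.children(x) if not isinstance(target, Switching) else target.children_on(x)
    if len(cs) != 2:
        return INF
    x1, x2 = cs
    return min(
        dist(x1, a1) + dist(x2, a2),
        dist(x1, a2) + dist(x2, a1),
    )


def validate_reconciliation(
    gene_tree: GeneTree,
    target,
    alpha_r: Mapping[int, int],
    alpha_e: Mapping[int, str],
    costs: CostParams | None = None,
) -> ValidationReport:
    """Check a reconciliation clause by clause and recompute its cost.

    The three clauses: (1) the contemporary event appears exactly at gene
    leaves, mapped to the species leaf of the same label; (2) a speciation
    image must have two separated paths to the child images; (3) descendants
    map below the image, strictly when the event is not a duplication.
    The third clause is checked on parent-child pairs, which implies it for
    all ancestor-descendant pairs by transitivity.
    """
    costs = costs or CostParams()
    leq, dist, meeting, net = _target_ops(target)
    for u in gene_tree.nodes:
        if u not in alpha_r or u not in alpha_e:
            raise ReconciliationError(f"gene node {u} is unmapped")

    def fail(msg: str) -> ValidationReport:
        return ValidationReport(valid=False, violation=msg)

    for u in gene_tree.nodes:
        ev = alpha_e[u]
        if gene_tree.is_leaf(u):
            if ev != CONTEMP_EVENT:
                return fail(f"leaf {u} has event {ev}, expected {CONTEMP_EVENT}")
            x = alpha_r[u]
            if net.kind.get(x) != LEAF:
                return fail(f"leaf {u} mapped to non-leaf node {x}")
            if net.leaf_label[x] != gene_tree.leaf_label[u]:
                return fail(
                    f"leaf {u} ({gene_tree.leaf_label[u]!r}) mapped to leaf {x} "
                    f"({net.leaf_label[x]!r}): label mismatch"
                )
        else:
            if ev == CONTEMP_EVENT:
                return fail(f"internal node {u} has the contemporary event")
            u1, u2 = gene_tree.children[u]
            if ev == SPEC_EVENT:
                if alpha_r[u] not in meeting(alpha_r[u1], alpha_r[u2]):
                    return fail(
                        f"speciation at {u}: image {alpha_r[u]} has no separated "
                        f"paths to images of {u1} and {u2}"
                    )
            for c in (u1, u2):
                if not leq(alpha_r[c], alpha_r[u]):
                    return fail(
                        f"child {c} maps to {alpha_r[c]}, not below image "
                        f"{alpha_r[u]} of {u}"
                    )
                if ev != DUP_EVENT and alpha_r[c] == alpha_r[u]:
                    return fail(
                        f"non-duplication at {u}: child {c} maps to the same node"
                    )
    losses: dict[int, float] = {}
    d = 0
    for u in gene_tree.internal:
        u1, u2 = gene_tree.children[u]
        losses[u] = event_losses(target, alpha_r, u, u1, u2, alpha_e[u])
        if alpha_e[u] == DUP_EVENT:
            d += 1
    total_l = sum(losses.values())
    cost = d * costs.dup + total_l * costs.loss
    return ValidationReport(
        valid=True, violation=None, d=d, l=total_l, cost=cost, losses=losses
    )
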