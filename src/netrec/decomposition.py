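"""Biconnected-component machinery.

Contracting every non-trivial biconnected component of a species network to
its root yields a tree ``bc(N)``.  Each remaining node stands for a
*component*: either a non-trivial blob (with one or more hybridization
nodes) or a single tree-like node.  Every non-leaf component ``B`` defines
an *elementary network* ``N(B)``: the component plus the cut-edges leaving
it, whose leaves are the roots of the child components.  Switchings of the
whole network factor exactly into independent switchings of the elementary
networks, which is what makes the best-switching search fixed-parameter
tractable in the network level.

The gene tree is lifted to an *augmented tree*: on each gene-tree edge, one
artificial (unary) node is inserted per component strictly between the
component labels of the two endpoints, so that consecutive nodes of the
augmented tree always sit in identical or adjacent components.  Grouping the
augmented tree by component yields per-component forests whose members are
binary trees or single edges hanging from an artificial node.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx

from .model import (
    GeneTree,
    Network,
    NetworkError,
    Switching,
)


@dataclass
class Component:
    """A node of ``bc(N)``: a blob or a single tree-like node.

    ``rep`` is the root node of the component in the host network and serves
    as the component's id.
    """

    rep: int
    nodes: frozenset[int]
    is_trivial: bool
    hyb_count: int
    is_leaf: bool

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Component(rep={self.rep}, |nodes|={len(self.nodes)})"


class ComponentDecomposition:
    """Components of a network, the tree ``bc(N)`` over them, and the
    elementary networks of the non-leaf components."""

    def __init__(self, network: Network):
        self.network = network
        g = network.graph
        und = g.to_undirected()
        nontrivial = [c for c in nx.biconnected_components(und) if len(c) >= 3]
        # Component membership: a node belongs to the blob it is a non-root
        # member of; blob roots and untouched nodes are their own component.
        self.node_component: dict[int, int] = {v: v for v in g}
        comps: dict[int, Component] = {}
        for blob in nontrivial:
            roots = [
                v for v in blob if not any(p in blob for p in g.predecessors(v))
            ]
            if len(roots) != 1:
                raise NetworkError(
                    f"biconnected component {sorted(blob)} has roots {roots}"
                )
            rep = roots[0]
            hyb = sum(
                1
                for v in blob
                if network.kind[v] == "hybridization"
                and all(p in blob for p in g.predecessors(v))
            )
            comps[rep] = Component(
                rep=rep,
                nodes=frozenset(blob),
                is_trivial=False,
                hyb_count=hyb,
                is_leaf=False,
            )
            for v in blob:
                if v != rep:
                    self.node_component[v] = rep
        for v in g:
            if self.node_component[v] == v and v not in comps:
                comps[v] = Component(
                    rep=v,
                    nodes=frozenset([v]),
                    is_trivial=True,
                    hyb_count=0,
                    is_leaf=network.kind[v] == "leaf",
                )
        self.components = comps
        # bc(N): edge rep(a) -> b for every cut-edge (a, b); binarity ensures
        # a cut-edge always enters a component at its root.
        bc = nx.DiGraph()
        bc.add_nodes_from(comps)
        for a, b in g.edges:
            ra, rb = self.node_component[a], self.node_component[b]
            if ra == rb:
                continue
            if rb != b:
                raise NetworkError(
                    f"cut-edge ({a}, {b}) enters component {rb} off its root"
                )
            bc.add_edge(ra, b)
        self.bc_tree = bc
        self.bc_parent: dict[int, int] = {}
        for a, b in bc.edges:
            self.bc_parent[b] = a
        self.bc_root = self.node_component[network.root]
        self.bc_depth: dict[int, int] = {self.bc_root: 0}
        for v in nx.topological_sort(bc):
            for c in bc.successors(v):
                self.bc_depth[c] = self.bc_depth[v] + 1
        self._elementary: dict[int, Network] = {}

    # -- bc-tree relations --------------------------------------------------

    @property
    def level(self) -> int:
        return max((c.hyb_count for c in self.components.values()), default=0)

    @property
    def nonleaf_components(self) -> list[int]:
        return sorted(r for r, c in self.components.items() if not c.is_leaf)

    def component_of(self, node: int) -> int:
        return self.node_component[node]

    def bc_lca(self, a: int, b: int) -> int:
        while self.bc_depth[a] > self.bc_depth[b]:
            a = self.bc_parent[a]
        while self.bc_depth[b] > self.bc_depth[a]:
            b = self.bc_parent[b]
        while a != b:
            a = self.bc_parent[a]
            b = self.bc_parent[b]
        return a

    def bc_path_up(self, low: int, high: int) -> list[int]:
        """Components strictly between ``low`` and ``high``, bottom to top."""
        out = []
        v = low
        while v != high:
            if v not in self.bc_parent:
                raise NetworkError(f"component {high} is not above {low}")
            v = self.bc_parent[v]
            if v != high:
                out.append(v)
        return out

    # -- elementary networks -------------------------------------------------

    def elementary_network(self, rep: int) -> Network:
        """The component plus its outgoing cut-edges, as a standalone network.

        Node ids are shared with the host network; the leaves (targets of the
        cut-edges, i.e. child-component roots) are labelled by their id.
        """
        if rep in self._elementary:
            return self._elementary[rep]
        comp = self.components[rep]
        if comp.is_leaf:
            raise NetworkError(f"component {rep} is a leaf of the network")
        g = self.network.graph
        edges = []
        leaf_labels = {}
        for v in comp.nodes:
            for c in g.successors(v):
                edges.append((v, c))
                if self.node_component[c] != rep:
                    leaf_labels[c] = str(c)
        net = Network(nx.DiGraph(edges), leaf_labels)
        self._elementary[rep] = net
        return net


def decompose(network: Network) -> ComponentDecomposition:
    """Compute the component decomposition of a validated network."""
    return ComponentDecomposition(network)


@dataclass
class AugmentedGeneTree:
    """The gene tree with artificial unary nodes, labelled by components.

    ``children`` maps every non-leaf node to its children (artificial nodes
    have exactly one); ``component`` maps every node to the rep of its
    component; ``orig`` maps non-artificial nodes back to gene-tree ids.
    """

    root: int
    children: dict[int, tuple[int, ...]]
    parent: dict[int, int]
    component: dict[int, int]
    orig: dict[int, int]  # augmented id -> gene-tree id (non-artificial only)
    artificial: frozenset[int]

    @property
    def nodes(self) -> list[int]:
        return sorted(self.component)

    def is_leaf(self, u: int) -> bool:
        return u not in self.children


def compute_B_mapping(
    gene_tree: GeneTree, network: Network, dec: ComponentDecomposition
) -> AugmentedGeneTree:
    """Label gene-tree nodes by components and insert artificial nodes.

    A leaf is labelled by the component of the species leaf it names; an
    internal node by the lowest component whose subnetwork spans its leaf
    labels, i.e. the ``bc(N)``-LCA of the children's components.  One
    artificial node is then inserted per component skipped along an edge.
    The gene tree must be normalized (no single-species internal subtree).
    """
    comp_of_gene: dict[int, int] = {}
    for u in gene_tree.postorder():
        if gene_tree.is_leaf(u):
            lab = gene_tree.leaf_label[u]
            if lab not in network.label_to_leaf:
                raise NetworkError(f"gene leaf label {lab!r} absent from network")
            comp_of_gene[u] = dec.component_of(network.label_to_leaf[lab])
        else:
            a, b = gene_tree.children[u]
            comp_of_gene[u] = dec.bc_lca(comp_of_gene[a], comp_of_gene[b])

    counter = itertools.count()
    children: dict[int, tuple[int, ...]] = {}
    parent: dict[int, int] = {}
    component: dict[int, int] = {}
    orig: dict[int, int] = {}
    artificial: set[int] = set()
    gene_to_aug: dict[int, int] = {}

    for u in gene_tree.nodes:
        nid = next(counter)
        gene_to_aug[u] = nid
        component[nid] = comp_of_gene[u]
        orig[nid] = u

    for u in gene_tree.internal:
        kids = []
        for c in gene_tree.children[u]:
            chain = dec.bc_path_up(comp_of_gene[c], comp_of_gene[u])
            top = gene_to_aug[c]
            # chain is bottom-to-top; build artificial nodes downwards.
            for comp in chain:
                nid = next(counter)
                artificial.add(nid)
                component[nid] = comp
                children[nid] = (top,)
                parent[top] = nid
                top = nid
            kids.append(top)
            parent[top] = gene_to_aug[u]
        children[gene_to_aug[u]] = tuple(kids)
    return AugmentedGeneTree(
        root=gene_to_aug[gene_tree.root],
        children=children,
        parent=parent,
        component=component,
        orig=orig,
        artificial=frozenset(artificial),
    )


@dataclass
class ForestMember:
    """One maximal subgraph of the augmented tree within a component.

    Either a binary tree (``is_edge`` false) or a single edge whose upper
    extremity is an artificial node.  ``leaves`` are augmented-tree nodes
    whose component is a child of this member's component; ``leaf_component``
    gives that child component per leaf.
    """

    component: int
    root: int
    children: dict[int, tuple[int, ...]]
    leaves: list[int]
    leaf_component: dict[int, int]
    is_edge: bool

    def internal_nodes(self) -> list[int]:
        return sorted(self.children)


def build_component_forest(
    aug: AugmentedGeneTree, dec: ComponentDecomposition
) -> dict[int, list[ForestMember]]:
    """Group the augmented tree into per-component forests.

    For each non-leaf component, the maximal connected subgraphs whose
    internal nodes all carry that component label.  Every internal node of
    the augmented tree lands in exactly one member.
    """
    forests: dict[int, list[ForestMember]] = {
        rep: [] for rep in dec.nonleaf_components
    }
    members: dict[int, set[int]] = {rep: set() for rep in dec.nonleaf_components}
    for u in aug.nodes:
        if not aug.is_leaf(u):
            members[aug.component[u]].add(u)
    for rep in dec.nonleaf_components:
        nodes = members[rep]
        seen: set[int] = set()
        for u in sorted(nodes):
            if u in seen:
                continue
            # Walk to the top of this connected group.
            top = u
            while top in aug.parent and aug.parent[top] in nodes:
                top = aug.parent[top]
            group: set[int] = set()
            stack = [top]
            while stack:
                v = stack.pop()
                group.add(v)
                for c in aug.children.get(v, ()):
                    if c in nodes:
                        stack.append(c)
            seen |= group
            children: dict[int, tuple[int, ...]] = {}
            leaves: list[int] = []
            leaf_component: dict[int, int] = {}
            for v in group:
                children[v] = aug.children[v]
                for c in aug.children[v]:
                    if c not in group:
                        leaves.append(c)
                        leaf_component[c] = aug.component[c]
            is_edge = len(group) == 1 and next(iter(group)) in aug.artificial
            forests[rep].append(
                ForestMember(
                    component=rep,
                    root=top,
                    children=children,
                    leaves=sorted(leaves),
                    leaf_component=leaf_component,
                    is_edge=is_edge,
                )
            )
        forests[rep].sort(key=lambda m: m.root)
    return forests


def enumerate_switchings(elementary: Network) -> list[Switching]:
    """All distinct switchings of an elementary network.

    One incoming-edge choice per hybridization node, closure applied, and
    post-closure duplicates removed; the order is deterministic
    (lexicographic over hybridization node id and chosen parent id).
    """
    hybs = elementary.hybridization_nodes
    choice_lists = [[(h, p) for p in elementary.parents(h)] for h in hybs]
    out: list[Switching] = []
    seen: set[tuple] = set()
    for combo in itertools.product(*choice_lists):
        sw = Switching.from_choices(elementary, dict(combo))
        key = sw.sort_key()
        if key not in seen:
            seen.add(key)
            out.append(sw)
    return out


def assemble_switching(
    network: Network,
    dec: ComponentDecomposition,
    choices: Mapping[int, Switching],
) -> Switching:
    """Combine per-component switchings into a global one.

    ``choices`` maps component reps (of components containing hybridization
    nodes) to switchings of their elementary networks.  The global closure is
    re-run and the restriction to every elementary network is verified to
    match the chosen switching.
    """
    hyb_choice: dict[int, int] = {}
    for rep, comp in dec.components.items():
        if comp.hyb_count == 0:
            continue
        if rep not in choices:
            raise NetworkError(f"missing switching choice for component {rep}")
        sw = choices[rep]
        for h in sw.network.hybridization_nodes:
            hyb_choice[h] = sw.choices[h]
    global_sw = Switching.from_choices(network, hyb_choice)
    for rep, sw in choices.items():
        local_edges = set(sw.network.graph.edges)
        expected_off = {e for e in global_sw.off_edges if e in local_edges}
        if expected_off != set(sw.off_edges):
            raise NetworkError(
                f"switching of component {rep} does not match the global closure"
            )
    return global_sw
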