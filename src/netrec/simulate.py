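"""Random instance generation with known ground truth, and the brute-force
oracles the algorithmic modules are checked against.

The network generator grows a random binary species tree and repeatedly
subdivides two tree edges, joining them by a new reticulation edge whenever
that keeps the graph acyclic.  The gene-tree simulator picks a uniform
random switching, then evolves a single gene lineage down its displayed
tree: at every speciation node untouched by switched-off edges the lineage
may duplicate (both copies continue at the node) and each copy descending a
child branch may be lost.  Extinct parts are pruned and the surviving
history is returned together with the reconciliation it induces, whose
duplication and loss counts certify an upper bound on the parsimony cost.

The oracles deliberately avoid the candidate-set machinery: the
best-switching oracle enumerates every global switching; the network oracle
searches the full space of event-valid reconciliations, organised as a
table over (gene node, image node) pairs, with no restriction to minimal
meeting sets or to duplications at the higher child image.  A literal
enumerator over all image assignments is provided for very small instances
to vouch for the table-based search itself.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass

import networkx as nx

from .model import (
    CONTEMP_EVENT,
    DUP_EVENT,
    INF,
    SPEC_EVENT,
    CostParams,
    GeneTree,
    Network,
    NetworkError,
    Switching,
    validate_network,
    validate_reconciliation,
)
from .treerec import lca_reconcile


# ---------------------------------------------------------------------------
# generators


def random_network(
    n_leaves: int, n_hybridizations: int, seed: int | random.Random
) -> Network:
    """A random binary network with the requested number of reticulations.

    Starts from a random binary tree on ``n_leaves`` leaves (labelled
    ``s1..sn``), then adds reticulation edges between subdivided edge pairs,
    rejecting choices that would create a cycle.  Deterministic in the seed.
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    if n_hybridizations < 0:
        raise ValueError("negative hybridization count")
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    counter = itertools.count()
    leaves = [next(counter) for _ in range(n_leaves)]
    labels = {v: f"s{i + 1}" for i, v in enumerate(leaves)}
    g = nx.DiGraph()
    g.add_nodes_from(leaves)
    roots = list(leaves)
    while len(roots) > 1:
        i, j = sorted(rng.sample(range(len(roots)), 2))
        b = roots.pop(j)
        a = roots.pop(i)
        v = next(counter)
        g.add_edge(v, a)
        g.add_edge(v, b)
        roots.append(v)
    added = 0
    attempts = 0
    max_attempts = 200 * max(1, n_hybridizations)
    while added < n_hybridizations:
        attempts += 1
        if attempts > max_attempts:
            raise NetworkError(
                f"could not place {n_hybridizations} reticulations after "
                f"{max_attempts} attempts"
            )
        edges = sorted(g.edges)
        e1 = edges[rng.randrange(len(edges))]
        e2 = edges[rng.randrange(len(edges))]
        if e1 == e2:
            continue
        (a, b), (c, d) = e1, e2
        # New edge runs s -> t with s on e1 and t on e2; a cycle appears
        # exactly when a is reachable from d (or coincides with it).
        if a == d or nx.has_path(g, d, a):
            continue
        s, t = next(counter), next(counter)
        g.remove_edge(a, b)
        g.remove_edge(c, d)
        g.add_edges_from([(a, s), (s, b), (c, t), (t, d), (s, t)])
        added += 1
    return validate_network(g.edges, labels)


def random_gene_tree(
    species: list[str], n_leaves: int, seed: int | random.Random
) -> GeneTree:
    """A random binary gene tree whose leaves sample species with
    replacement (several gene copies per species are possible)."""
    if n_leaves < 1:
        raise ValueError("need at least 1 leaf")
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    species = sorted(species)
    counter = itertools.count()
    labels: dict[int, str] = {}
    children: dict[int, tuple[int, ...]] = {}
    roots = []
    for _ in range(n_leaves):
        v = next(counter)
        labels[v] = rng.choice(species)
        roots.append(v)
    while len(roots) > 1:
        i, j = sorted(rng.sample(range(len(roots)), 2))
        b = roots.pop(j)
        a = roots.pop(i)
        v = next(counter)
        children[v] = (a, b)
        roots.append(v)
    return GeneTree(children, labels, roots[0])


def random_switching(network: Network, seed: int | random.Random) -> Switching:
    """A uniform random choice of on-parent per hybridization node."""
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    choices = {
        h: rng.choice(network.parents(h)) for h in network.hybridization_nodes
    }
    return Switching.from_choices(network, choices)


# ---------------------------------------------------------------------------
# gene-family simulation


@dataclass
class SimulationRecord:
    """A simulated gene family with its true switching and event history.

    ``d_true`` and ``l_true`` are the duplication and loss counts of the
    reconciliation induced by the surviving lineages, so
    ``dup_cost * d_true + loss_cost * l_true`` upper-bounds the parsimony
    cost of the gene tree on the true switching.  ``raw_duplications`` and
    ``raw_losses`` also count events in lineages that later went extinct.
    """

    seed: int
    network: Network
    switching: Switching
    gene_tree: GeneTree
    alpha_r: dict[int, int]
    alpha_e: dict[int, str]
    d_true: int
    l_true: float
    raw_duplications: int
    raw_losses: int
    dup_rate: float
    loss_rate: float


def simulate_gene_tree(
    network: Network,
    dup_rate: float,
    loss_rate: float,
    seed: int,
    max_retries: int = 200,
) -> SimulationRecord:
    """Evolve one gene lineage down a random switching of the network.

    At every speciation-or-root node in ``V_on`` a lineage duplicates with
    probability ``dup_rate`` (recursively, so bursts are possible) and each
    copy entering a child branch is lost with probability ``loss_rate``;
    off-path and hybridization nodes are passed through silently.  Histories
    whose surviving gene tree has fewer than two leaves are rejected and
    redrawn, up to ``max_retries`` times.
    """
    if not (0 <= dup_rate < 1) or not (0 <= loss_rate < 1):
        raise ValueError("rates must lie in [0, 1)")
    rng = random.Random(seed)
    sw = random_switching(network, rng)
    raw = {"dup": 0, "loss": 0}

    def evolve(v: int, depth: int = 0):
        # Returns a history node: ("leaf", x) | ("spec"/"dup", x, kids)
        if depth > 10000:
            raise NetworkError("runaway duplication burst")
        kind = network.kind[v]
        if kind == "leaf":
            return ("leaf", v)
        on_kids = sw.children_on(v)
        if v in sw.v_on and network.is_counted(v):
            if rng.random() < dup_rate:
                raw["dup"] += 1
                left = evolve(v, depth + 1)
                right = evolve(v, depth + 1)
                return ("dup", v, [left, right])
            kids = []
            for c in on_kids:
                if rng.random() < loss_rate:
                    raw["loss"] += 1
                else:
                    kids.append(evolve(c, depth + 1))
            return ("spec", v, kids)
        (c,) = on_kids
        return evolve(c, depth + 1)

    for _ in range(max_retries):
        raw["dup"] = raw["loss"] = 0
        history = evolve(network.root)
        pruned = _prune(history)
        if pruned is None:
            continue
        counter = itertools.count()
        children: dict[int, tuple[int, ...]] = {}
        labels: dict[int, str] = {}
        alpha_r: dict[int, int] = {}
        alpha_e: dict[int, str] = {}

        def build(node) -> int:
            nid = next(counter)
            if node[0] == "leaf":
                labels[nid] = network.leaf_label[node[1]]
                alpha_r[nid] = node[1]
                alpha_e[nid] = CONTEMP_EVENT
            else:
                kind, x, kids = node
                children[nid] = tuple(build(k) for k in kids)
                alpha_r[nid] = x
                alpha_e[nid] = DUP_EVENT if kind == "dup" else SPEC_EVENT
            return nid

        root = build(pruned)
        if len(labels) < 2:
            continue
        tree = GeneTree(children, labels, root)
        report = validate_reconciliation(tree, sw, alpha_r, alpha_e)
        if not report.valid:  # pragma: no cover - guards the simulator itself
            raise NetworkError(f"simulated history invalid: {report.violation}")
        return SimulationRecord(
            seed=seed,
            network=network,
            switching=sw,
            gene_tree=tree,
            alpha_r=alpha_r,
            alpha_e=alpha_e,
            d_true=report.d,
            l_true=report.l,
            raw_duplications=raw["dup"],
            raw_losses=raw["loss"],
            dup_rate=dup_rate,
            loss_rate=loss_rate,
        )
    raise NetworkError(f"extinction in every one of {max_retries} attempts")


def _prune(node):
    """Drop extinct lineages and suppress single-child history nodes."""
    if node[0] == "leaf":
        return node
    kind, x, kids = node
    alive = [p for p in (_prune(k) for k in kids) if p is not None]
    if not alive:
        return None
    if len(alive) == 1:
        return alive[0]
    return (kind, x, alive)


# ---------------------------------------------------------------------------
# oracles


def enumerate_global_switchings(
    network: Network, guard_h: int = 12
) -> list[Switching]:
    """All distinct global switchings (post-closure deduplicated)."""
    if network.h > guard_h:
        raise NetworkError(
            f"{network.h} hybridization nodes exceed the enumeration guard "
            f"of {guard_h}"
        )
    hybs = network.hybridization_nodes
    out, seen = [], set()
    for combo in itertools.product(
        *[[(h, p) for p in network.parents(h)] for h in hybs]
    ):
        sw = Switching.from_choices(network, dict(combo))
        key = sw.sort_key()
        if key not in seen:
            seen.add(key)
            out.append(sw)
    return out


def oracle_best_switching(
    gene_tree: GeneTree,
    network: Network,
    costs: CostParams | None = None,
    guard_h: int = 12,
) -> float:
    """Minimum reconciliation cost over all switchings, by enumeration."""
    costs = costs or CostParams()
    return min(
        lca_reconcile(gene_tree, sw, costs).cost
        for sw in enumerate_global_switchings(network, guard_h)
    )


def oracle_reconcile_network(
    gene_tree: GeneTree, network: Network, costs: CostParams | None = None
) -> float:
    """Exhaustive minimum over all event-valid network reconciliations.

    Organised as a full table ``best[u][x]`` over every (gene node, network
    node) pair: speciation images range over the complete meeting set (not
    its minimal subset) and duplication images over every node above both
    child images (including hybridization nodes).  Validity constraints are
    local to parent-child pairs, so the table minimum is the true optimum.
    Single-species subtrees are collapsed and scored as duplications, the
    same convention the dynamic program uses.
    """
    costs = costs or CostParams()
    norm = gene_tree.normalize()
    tree = norm.tree
    nodes = network.nodes
    best: dict[int, dict[int, float]] = {}
    for u in tree.postorder():
        if tree.is_leaf(u):
            lab = tree.leaf_label[u]
            if lab not in network.label_to_leaf:
                raise NetworkError(f"gene leaf label {lab!r} absent from network")
            best[u] = {network.label_to_leaf[lab]: 0.0}
            continue
        u1, u2 = tree.children[u]
        b1, b2 = best[u1], best[u2]
        bu: dict[int, float] = {}
        for x in nodes:
            cands = []
            kids = network.children(x)
            if len(kids) == 2:
                x1, x2 = kids
                for y, c1 in b1.items():
                    for z, c2 in b2.items():
                        loss = min(
                            network.dist(x1, y) + network.dist(x2, z),
                            network.dist(x1, z) + network.dist(x2, y),
                        )
                        if loss < INF:
                            cands.append(c1 + c2 + costs.loss * loss)
            for y, c1 in b1.items():
                if not network.leq(y, x):
                    continue
                for z, c2 in b2.items():
                    if not network.leq(z, x):
                        continue
                    cands.append(
                        costs.dup
                        + c1
                        + c2
                        + costs.loss
                        * (network.dist(x, y) + network.dist(x, z))
                    )
            if cands:
                bu[x] = min(cands)
        if not bu:
            raise NetworkError(f"no feasible image for gene node {u}")
        best[u] = bu
    return (
        min(best[tree.root].values())
        + costs.dup * norm.n_collapsed_duplications
    )


def oracle_reconcile_exhaustive(
    gene_tree: GeneTree,
    network: Network,
    costs: CostParams | None = None,
    guard_internal: int = 3,
    guard_nodes: int = 14,
) -> float:
    """Literal enumeration of every image assignment and event labelling.

    Only feasible for tiny instances; used to vouch for the table-based
    oracle.  The gene tree must already be free of single-species internal
    subtrees.
    """
    costs = costs or CostParams()
    tree = gene_tree
    internal = tree.internal
    if len(internal) > guard_internal:
        raise NetworkError(
            f"{len(internal)} internal nodes exceed the guard of "
            f"{guard_internal}"
        )
    if len(network.nodes) > guard_nodes:
        raise NetworkError(
            f"{len(network.nodes)} network nodes exceed the guard of "
            f"{guard_nodes}"
        )
    leaf_r = {
        u: network.label_to_leaf[tree.leaf_label[u]] for u in tree.leaves
    }
    best = INF
    for images in itertools.product(network.nodes, repeat=len(internal)):
        alpha_r = dict(leaf_r)
        alpha_r.update(dict(zip(internal, images)))
        for events in itertools.product(
            (SPEC_EVENT, DUP_EVENT), repeat=len(internal)
        ):
            alpha_e = {u: CONTEMP_EVENT for u in tree.leaves}
            alpha_e.update(dict(zip(internal, events)))
            report = validate_reconciliation(
                tree, network, alpha_r, alpha_e, costs
            )
            if report.valid and report.cost < best:
                best = report.cost
    return best
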