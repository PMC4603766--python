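"""LCA reconciliation on trees and switchings, and per-component costs.

On a tree (or a switching, which behaves as a tree over its switched-on
edges) the unique minimum-cost duplication-loss reconciliation maps every
leaf to the species leaf of the same label and every internal node to the
LCA of its children's images; the event is a duplication exactly when the
children's images are comparable.  Losses are counted with the switching-
aware loss distance.

The per-component cost charges each member of a component forest against a
switching of the component's elementary network: binary-tree members pay
their LCA-reconciliation cost (plus, outside the root component, the losses
from the elementary root down to the member root's image); edge members pay
only those root-path losses.  Summed over components, these costs equal the
plain reconciliation cost against the assembled global switching, which is
the identity making per-component minimization sound.
"""

from __future__ import annotations

from typing import Callable, Mapping, Sequence

from .decomposition import ForestMember
from .model import (
    CONTEMP_EVENT,
    DUP_EVENT,
    SPEC_EVENT,
    CostParams,
    GeneTree,
    NetworkError,
    Reconciliation,
    Switching,
    event_losses,
)


def _member_postorder(member: ForestMember) -> list[int]:
    out: list[int] = []
    stack = [(member.root, False)]
    while stack:
        u, done = stack.pop()
        if done or u not in member.children:
            out.append(u)
        else:
            stack.append((u, True))
            for c in reversed(member.children[u]):
                stack.append((c, False))
    return out


def _lca_reconcile_generic(
    postorder: Sequence[int],
    is_leaf: Callable[[int], bool],
    children: Callable[[int], Sequence[int]],
    leaf_image: Callable[[int], int],
    switching: Switching,
    costs: CostParams,
) -> Reconciliation:
    alpha_r: dict[int, int] = {}
    alpha_e: dict[int, str] = {}
    losses: dict[int, float] = {}
    d = 0
    for u in postorder:
        if is_leaf(u):
            alpha_r[u] = leaf_image(u)
            alpha_e[u] = CONTEMP_EVENT
            continue
        kids = children(u)
        if len(kids) == 1:
            # Artificial pass-through (only occurs in augmented trees).
            (c,) = kids
            alpha_r[u] = alpha_r[c]
            alpha_e[u] = alpha_e[c]
            continue
        u1, u2 = kids
        a1, a2 = alpha_r[u1], alpha_r[u2]
        x = switching.lca(a1, a2)
        alpha_r[u] = x
        if switching.leq(a1, a2) or switching.leq(a2, a1):
            alpha_e[u] = DUP_EVENT
            d += 1
        else:
            alpha_e[u] = SPEC_EVENT
        losses[u] = event_losses(switching, alpha_r, u, u1, u2, alpha_e[u])
    total_l = sum(losses.values())
    return Reconciliation(
        alpha_r=alpha_r,
        alpha_e=alpha_e,
        losses=losses,
        d=d,
        l=total_l,
        cost=d * costs.dup + total_l * costs.loss,
    )


def lca_reconcile(
    gene_tree: GeneTree,
    switching: Switching,
    costs: CostParams | None = None,
    leaf_map: Mapping[int, int] | None = None,
) -> Reconciliation:
    """The minimum-cost reconciliation of a gene tree onto a switching.

    Leaves map to the switching leaf of the same species label unless a
    ``leaf_map`` (gene leaf -> network node) overrides them.
    """
    costs = costs or CostParams()

    def leaf_image(u: int) -> int:
        if leaf_map is not None:
            return leaf_map[u]
        lab = gene_tree.leaf_label[u]
        if lab not in switching.network.label_to_leaf:
            raise NetworkError(f"gene leaf label {lab!r} absent from the network")
        return switching.leaf_of_label(lab)

    return _lca_reconcile_generic(
        gene_tree.postorder(),
        gene_tree.is_leaf,
        lambda u: gene_tree.children[u],
        leaf_image,
        switching,
        costs,
    )


def beta_reconcile(
    member: ForestMember,
    elementary_switching: Switching,
    costs: CostParams | None = None,
) -> Reconciliation:
    """LCA-reconcile a binary-tree forest member onto a component switching.

    Each member leaf is pre-mapped to the root of its (child) component,
    which is a leaf of the elementary network.
    """
    if member.is_edge:
        raise NetworkError("an edge member has no internal structure to reconcile")
    costs = costs or CostParams()
    return _lca_reconcile_generic(
        _member_postorder(member),
        lambda u: u not in member.children,
        lambda u: member.children[u],
        lambda u: member.leaf_component[u],
        elementary_switching,
        costs,
    )


def component_cost(
    member: ForestMember,
    elementary_switching: Switching,
    costs: CostParams | None = None,
    is_root_component: bool = False,
) -> float:
    """Contribution of one forest member to the cost of a global switching.

    Tree members: their reconciliation cost, plus (outside the component of
    the gene-tree root) loss costs from the elementary root down to the image
    of the member's root.  Edge members: only those root-path losses, down to
    the root of the child component that the edge traverses into.
    """
    costs = costs or CostParams()
    sw = elementary_switching
    r = sw.network.root
    if member.is_edge:
        (leaf,) = member.leaves
        target = member.leaf_component[leaf]
        return costs.loss * sw.dist(r, target)
    recon = beta_reconcile(member, sw, costs)
    total = recon.cost
    if not is_root_component:
        total += costs.loss * sw.dist(r, recon.alpha_r[member.root])
    return total
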