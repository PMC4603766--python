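"""Reading and writing gene trees (Newick), species networks (extended
Newick) and reconciliation reports (TSV / JSON).

The extended-Newick dialect follows the common convention for hybridization
tags: each ``#H<n>`` label appears exactly twice, the occurrence carrying a
subtree defines the hybridization node's child and the bare occurrence is the
second parent attachment.  The parser is hand-written because gene trees here
may repeat leaf labels (several gene copies per species) and hybrid tags are
not part of plain Newick; it reports 0-based character positions on errors.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

from .model import (
    CostParams,
    GeneTree,
    GeneTreeError,
    Network,
    NetworkError,
    Switching,
    validate_network,
)


class ParseError(ValueError):
    """Malformed Newick/eNewick input, with the character position."""

    def __init__(self, message: str, pos: int):
        super().__init__(f"{message} (at position {pos})")
        self.pos = pos


_NAME_RE = re.compile(r"[^(),;:\s\[\]]+")


@dataclass
class _RawNode:
    nid: int
    name: str
    children: list["_RawNode"] = field(default_factory=list)


class _NewickParser:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0
        self.counter = 0

    def _skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def _peek(self) -> str:
        self._skip_ws()
        if self.pos >= len(self.text):
            raise ParseError("unexpected end of input", self.pos)
        return self.text[self.pos]

    def _fresh(self, name: str) -> _RawNode:
        node = _RawNode(self.counter, name)
        self.counter += 1
        return node

    def _read_name(self) -> str:
        self._skip_ws()
        m = _NAME_RE.match(self.text, self.pos)
        if not m:
            return ""
        self.pos = m.end()
        return m.group(0)

    def _skip_length(self) -> None:
        self._skip_ws()
        if self.pos < len(self.text) and self.text[self.pos] == ":":
            self.pos += 1
            m = re.match(r"[-+0-9.eE]+", self.text[self.pos :])
            if not m:
                raise ParseError("malformed branch length", self.pos)
            self.pos += m.end()

    def parse(self) -> _RawNode:
        root = self._subtree()
        self._skip_ws()
        if self.pos >= len(self.text) or self.text[self.pos] != ";":
            raise ParseError("expected ';' terminating the tree", self.pos)
        self.pos += 1
        self._skip_ws()
        if self.pos != len(self.text):
            raise ParseError("trailing characters after ';'", self.pos)
        return root

    def _subtree(self) -> _RawNode:
        if self._peek() == "(":
            open_pos = self.pos
            self.pos += 1
            node = self._fresh("")
            node.children.append(self._subtree())
            while self._peek() == ",":
                self.pos += 1
                node.children.append(self._subtree())
            if self._peek() != ")":
                raise ParseError("unbalanced '(' ", open_pos)
            self.pos += 1
            node.name = self._read_name()
            self._skip_length()
            return node
        start = self.pos
        name = self._read_name()
        if not name:
            raise ParseError("expected a leaf name", start)
        node = self._fresh(name)
        self._skip_length()
        return node


def _hybrid_tag(name: str) -> str | None:
    if "#" in name:
        return name[name.index("#") :]
    return None


def read_newick_gene_tree(text: str) -> GeneTree:
    """Parse a rooted binary Newick gene tree.

    Leaf names are species labels; duplicates are allowed (several gene
    copies in one species).  Polytomies, including the implicit trifurcation
    of unrooted Newick, are rejected.
    """
    root = _NewickParser(text).parse()
    children: dict[int, list[int]] = {}
    labels: dict[int, str] = {}
    stack = [root]
    while stack:
        node = stack.pop()
        if _hybrid_tag(node.name):
            raise ParseError(
                f"hybrid tag {node.name!r} is not allowed in a gene tree", 0
            )
        if node.children:
            if len(node.children) != 2:
                raise GeneTreeError(
                    f"polytomy: node has {len(node.children)} children "
                    "(is the tree unrooted?)"
                )
            children[node.nid] = [c.nid for c in node.children]
            stack.extend(node.children)
        else:
            if not node.name:
                raise GeneTreeError("unnamed leaf")
            labels[node.nid] = node.name
    return GeneTree(children, labels, root.nid)


def read_enewick_network(text: str) -> Network:
    """Parse an extended-Newick species network and validate it.

    Each ``#H<n>`` hybrid tag must appear exactly twice, once carrying the
    hybridization node's subtree and once bare (the second parent).
    """
    root = _NewickParser(text).parse()
    occurrences: dict[str, list[_RawNode]] = {}
    order: list[_RawNode] = []
    stack = [root]
    while stack:
        node = stack.pop()
        order.append(node)
        tag = _hybrid_tag(node.name)
        if tag is not None:
            occurrences.setdefault(tag, []).append(node)
        stack.extend(node.children)
    canonical: dict[int, int] = {}
    for tag, occ in occurrences.items():
        if len(occ) != 2:
            raise NetworkError(
                f"hybrid tag {tag!r} appears {len(occ)} time(s), expected 2"
            )
        with_child = [n for n in occ if n.children]
        if len(with_child) != 1:
            raise NetworkError(
                f"hybrid tag {tag!r} must carry a subtree exactly once"
            )
        rep = min(occ, key=lambda n: n.nid)
        for n in occ:
            canonical[n.nid] = rep.nid
    edges: list[tuple[int, int]] = []
    labels: dict[int, str] = {}
    stack = [root]
    while stack:
        node = stack.pop()
        nid = canonical.get(node.nid, node.nid)
        for c in node.children:
            cid = canonical.get(c.nid, c.nid)
            edges.append((nid, cid))
            stack.append(c)
        if not node.children and _hybrid_tag(node.name) is None:
            labels[node.nid] = node.name
    return validate_network(edges, labels)


def write_gene_tree(tree: GeneTree) -> str:
    def emit(u: int) -> str:
        if tree.is_leaf(u):
            return tree.leaf_label[u]
        a, b = tree.children[u]
        return f"({emit(a)},{emit(b)})"

    return emit(tree.root) + ";"


def write_network_enewick(network: Network) -> str:
    """Serialize a network to extended Newick (hybrid tags ``#H1``, ...)."""
    tags: dict[int, str] = {
        v: f"#H{i + 1}" for i, v in enumerate(network.hybridization_nodes)
    }
    emitted: set[int] = set()

    def emit(v: int) -> str:
        if v in tags:
            if v in emitted:
                return tags[v]
            emitted.add(v)
            (child,) = network.children(v)
            return f"({emit(child)}){tags[v]}"
        kind = network.kind[v]
        if kind == "leaf":
            return network.leaf_label[v]
        a, b = network.children(v)
        return f"({emit(a)},{emit(b)})"

    return emit(network.root) + ";"


def displayed_tree(switching: Switching) -> GeneTree:
    """The tree displayed by a switching: off edges removed, unary nodes
    suppressed.  Returned as a species-leaf-labelled :class:`GeneTree`."""
    net = switching.network
    children: dict[int, list[int]] = {}
    labels: dict[int, str] = {}

    def resolve(v: int) -> int:
        # Skip chains of single-on-child nodes.
        while True:
            if net.kind[v] == "leaf":
                return v
            kids = switching.children_on(v)
            if len(kids) == 1:
                v = kids[0]
            else:
                return v

    def build(v: int) -> int:
        v = resolve(v)
        if net.kind[v] == "leaf":
            labels[v] = net.leaf_label[v]
            return v
        kids = switching.children_on(v)
        children[v] = [build(c) for c in kids]
        return v

    root = build(net.root)
    return GeneTree(children, labels, root)


def write_switching(switching: Switching) -> str:
    """The displayed tree of a switching as plain Newick."""
    return write_gene_tree(displayed_tree(switching))


@dataclass
class ReconciliationReport:
    """Serializable result of either reconciliation problem.

    ``rows`` hold one entry per gene-tree node: (gene node id, image node id,
    event, losses).  For the best-switching problem the chosen switching is
    included as an edge on/off table plus its displayed tree.
    """

    problem: str  # "best-switching" | "network-dp"
    dup_cost: float
    loss_cost: float
    total_cost: float
    duplications: int
    losses: float
    rows: list[tuple[int, int, str, float]]
    switching_edges: list[tuple[int, int, str]] | None = None
    displayed_tree: str | None = None

    def check_totals(self) -> None:
        d = sum(1 for _, _, e, _ in self.rows if e == "D")
        l = sum(loss for _, _, _, loss in self.rows)
        cost = d * self.dup_cost + l * self.loss_cost
        if d != self.duplications or l != self.losses or cost != self.total_cost:
            raise ValueError(
                f"report totals inconsistent with rows: d={d}, l={l}, cost={cost}"
            )

    def to_json(self) -> str:
        payload = {
            "problem": self.problem,
            "dup_cost": self.dup_cost,
            "loss_cost": self.loss_cost,
            "total_cost": self.total_cost,
            "duplications": self.duplications,
            "losses": self.losses,
            "rows": [list(r) for r in self.rows],
        }
        if self.switching_edges is not None:
            payload["switching_edges"] = [list(e) for e in self.switching_edges]
        if self.displayed_tree is not None:
            payload["displayed_tree"] = self.displayed_tree
        return json.dumps(payload, indent=2) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "ReconciliationReport":
        data = json.loads(text)
        return cls(
            problem=data["problem"],
            dup_cost=data["dup_cost"],
            loss_cost=data["loss_cost"],
            total_cost=data["total_cost"],
            duplications=data["duplications"],
            losses=data["losses"],
            rows=[tuple(r) for r in data["rows"]],
            switching_edges=(
                [tuple(e) for e in data["switching_edges"]]
                if "switching_edges" in data
                else None
            ),
            displayed_tree=data.get("displayed_tree"),
        )

    def to_tsv(self) -> str:
        lines = [
            f"# problem\t{self.problem}",
            f"# dup_cost\t{self.dup_cost}",
            f"# loss_cost\t{self.loss_cost}",
            f"# total_cost\t{self.total_cost}",
            f"# duplications\t{self.duplications}",
            f"# losses\t{self.losses}",
        ]
        if self.displayed_tree is not None:
            lines.append(f"# displayed_tree\t{self.displayed_tree}")
        lines.append("gene_node\timage_node\tevent\tlosses")
        for u, x, e, l in self.rows:
            lines.append(f"{u}\t{x}\t{e}\t{l}")
        return "\n".join(lines) + "\n"


def report_from_reconciliation(
    problem: str,
    costs: CostParams,
    recon,
    switching: Switching | None = None,
) -> ReconciliationReport:
    report = ReconciliationReport(
        problem=problem,
        dup_cost=costs.dup,
        loss_cost=costs.loss,
        total_cost=recon.cost,
        duplications=recon.d,
        losses=recon.l,
        rows=recon.rows(),
    )
    if switching is not None:
        report.switching_edges = [
            (a, b, "off" if (a, b) in switching.off_edges else "on")
            for a, b in sorted(switching.network.graph.edges)
        ]
        report.displayed_tree = write_switching(switching)
    report.check_totals()
    return report
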