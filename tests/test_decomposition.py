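"""Biconnected components, elementary networks, the component labelling of
the gene tree, component forests, and switching enumeration/assembly."""

from __future__ import annotations

import random
from collections import Counter

import pytest

import netrec as nr
from netrec.decomposition import (
    assemble_switching,
    build_component_forest,
    compute_B_mapping,
    decompose,
    enumerate_switchings,
)

from conftest import diamond_parts


def _series_diamonds():
    """Two one-hybridization blobs in series."""
    inner = "((P,(Q)#H2),(#H2,W))"
    return nr.read_enewick_network(f"((X,(Z)#H1),(#H1,{inner}));")


class TestDecompose:
    def test_tree_components_all_trivial(self):
        net = nr.read_enewick_network("((a,b),(c,d));")
        dec = decompose(net)
        assert all(c.is_trivial for c in dec.components.values())
        assert dec.level == 0
        # bc(N) is the network itself.
        assert set(dec.bc_tree.nodes) == set(net.nodes)
        assert set(dec.bc_tree.edges) == set(net.graph.edges)

    def test_diamond_single_blob(self, diamond):
        p = diamond_parts(diamond)
        dec = decompose(diamond)
        blobs = [c for c in dec.components.values() if not c.is_trivial]
        assert len(blobs) == 1
        assert blobs[0].nodes == {p["r"], p["a"], p["b"], p["h"]}
        assert blobs[0].rep == p["r"]
        assert dec.level == 1
        # Elementary network: the blob plus three leaf cut-edges.
        elem = dec.elementary_network(p["r"])
        assert sorted(elem.leaves) == sorted([p["X"], p["Y"], p["Z"]])

    def test_series_diamonds_two_blobs(self):
        net = _series_diamonds()
        dec = decompose(net)
        blobs = [c for c in dec.components.values() if not c.is_trivial]
        assert len(blobs) == 2
        assert net.h == 2 and net.level == 1

    def test_edges_partition_into_elementary_networks(self):
        rng = random.Random(31)
        for _ in range(30):
            net = nr.random_network(
                rng.randint(3, 9), rng.randint(0, 6), rng.randrange(2**30)
            )
            dec = decompose(net)
            counts = Counter()
            for rep in dec.nonleaf_components:
                counts.update(list(dec.elementary_network(rep).graph.edges))
            assert counts == Counter(list(net.graph.edges))


class TestComponentMapping:
    def test_congruent_mapping_has_no_artificial_nodes_on_tree(self):
        net = nr.read_enewick_network("((X,Y),C);")
        gene = nr.read_newick_gene_tree("((X,Y),C);")
        dec = decompose(net)
        aug = compute_B_mapping(gene, net, dec)
        assert not aug.artificial
        assert aug.component[aug.root] == net.root

    def test_diamond_cherries_map_to_blob(self, diamond):
        p = diamond_parts(diamond)
        dec = decompose(diamond)
        for newick in ("(X,Y);", "(X,Z);"):
            gene = nr.read_newick_gene_tree(newick)
            aug = compute_B_mapping(gene, diamond, dec)
            assert aug.component[aug.root] == p["r"]
            assert not aug.artificial

    def test_artificial_node_on_skipped_blob(self):
        # W hangs below the second blob; pairing it with X skips the first.
        net = _series_diamonds()
        gene = nr.read_newick_gene_tree("(W,Q);")
        dec = decompose(net)
        aug = compute_B_mapping(gene, net, dec)
        assert not aug.artificial  # both leaves inside the lower blob region
        gene2 = nr.read_newick_gene_tree("((P,Q),(X,Z));")
        aug2 = compute_B_mapping(gene2, net, dec)
        # the (P,Q) cherry maps into the lower blob; its edge from the root
        # (upper blob) must traverse the lower blob's root chain.
        assert aug2.component[aug2.root] == dec.bc_root

    def test_missing_species_raises(self, diamond):
        gene = nr.read_newick_gene_tree("(X,Q);")
        with pytest.raises(nr.NetworkError, match="Q"):
            compute_B_mapping(gene, diamond, decompose(diamond))

    def test_adjacency_invariant_on_random_instances(self):
        # Along every augmented-tree edge: an artificial node's component is
        # the parent of its child's and a child of its parent's; otherwise
        # the child's component equals the node's or is one of its children.
        rng = random.Random(32)
        for _ in range(40):
            net = nr.random_network(
                rng.randint(3, 8), rng.randint(0, 5), rng.randrange(2**30)
            )
            gene = nr.random_gene_tree(
                sorted(net.species), rng.randint(2, 8), rng.randrange(2**30)
            )
            norm = gene.normalize()
            dec = decompose(net)
            aug = compute_B_mapping(norm.tree, net, dec)
            for u, kids in aug.children.items():
                for c in kids:
                    bu, bc_ = aug.component[u], aug.component[c]
                    if u in aug.artificial:
                        assert dec.bc_parent[bc_] == bu
                    else:
                        assert bc_ == bu or dec.bc_parent.get(bc_) == bu

    def test_augmented_size_bound(self):
        rng = random.Random(33)
        for _ in range(20):
            net = nr.random_network(
                rng.randint(3, 8), rng.randint(0, 4), rng.randrange(2**30)
            )
            gene = nr.random_gene_tree(
                sorted(net.species), rng.randint(2, 8), rng.randrange(2**30)
            )
            norm = gene.normalize()
            dec = decompose(net)
            aug = compute_B_mapping(norm.tree, net, dec)
            p = len(dec.components)
            assert len(aug.nodes) <= len(norm.tree.nodes) * (1 + p)


class TestComponentForest:
    def test_root_component_forest_is_one_binary_tree(self):
        rng = random.Random(34)
        for _ in range(30):
            net = nr.random_network(
                rng.randint(3, 8), rng.randint(0, 5), rng.randrange(2**30)
            )
            gene = nr.random_gene_tree(
                sorted(net.species), rng.randint(2, 8), rng.randrange(2**30)
            )
            norm = gene.normalize()
            if norm.tree.is_leaf(norm.tree.root):
                continue
            dec = decompose(net)
            aug = compute_B_mapping(norm.tree, net, dec)
            forests = build_component_forest(aug, dec)
            root_comp = aug.component[aug.root]
            members = forests[root_comp]
            assert len(members) == 1
            assert not members[0].is_edge

    def test_members_partition_internal_nodes(self):
        rng = random.Random(35)
        for _ in range(30):
            net = nr.random_network(
                rng.randint(3, 8), rng.randint(0, 5), rng.randrange(2**30)
            )
            gene = nr.random_gene_tree(
                sorted(net.species), rng.randint(2, 8), rng.randrange(2**30)
            )
            norm = gene.normalize()
            dec = decompose(net)
            aug = compute_B_mapping(norm.tree, net, dec)
            forests = build_component_forest(aug, dec)
            seen = Counter()
            for members in forests.values():
                for m in members:
                    seen.update(m.internal_nodes())
                    if m.is_edge:
                        assert m.root in aug.artificial
                    for leaf in m.leaves:
                        assert (
                            dec.bc_parent[m.leaf_component[leaf]] == m.component
                        )
            internal = [u for u in aug.nodes if not aug.is_leaf(u)]
            assert seen == Counter(internal)


class TestSwitchings:
    def test_tree_component_has_one_switching(self):
        net = nr.read_enewick_network("((a,b),c);")
        dec = decompose(net)
        for rep in dec.nonleaf_components:
            assert len(enumerate_switchings(dec.elementary_network(rep))) == 1

    def test_diamond_component_has_two_switchings(self, diamond):
        dec = decompose(diamond)
        elem = dec.elementary_network(decompose(diamond).bc_root)
        assert len(enumerate_switchings(elem)) == 2

    def test_assemble_tree_identity(self):
        net = nr.read_enewick_network("((a,b),c);")
        dec = decompose(net)
        sw = assemble_switching(net, dec, {})
        assert not sw.off_edges

    def test_assemble_series_diamonds_left_left(self):
        net = _series_diamonds()
        dec = decompose(net)
        choices = {}
        for rep in dec.nonleaf_components:
            elem = dec.elementary_network(rep)
            if elem.h:
                choices[rep] = enumerate_switchings(elem)[0]
        sw = assemble_switching(net, dec, choices)
        shown = nr.displayed_tree(sw)
        assert sorted(shown.leaf_label.values()) == ["P", "Q", "W", "X", "Z"]
        # restriction of the global switching matches each component choice
        for rep, loc in choices.items():
            local_edges = set(loc.network.graph.edges)
            assert {e for e in sw.off_edges if e in local_edges} == set(
                loc.off_edges
            )

    def test_missing_choice_raises(self, diamond):
        dec = decompose(diamond)
        with pytest.raises(nr.NetworkError, match="missing"):
            assemble_switching(diamond, dec, {})
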