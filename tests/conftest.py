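"""Shared fixtures: canonical small instances and seeded random generators."""

from __future__ import annotations

import random

import pytest

import netrec as nr


@pytest.fixture
def costs():
    return nr.CostParams(1.0, 1.0)


@pytest.fixture
def diamond():
    """Root r -> a, b; a -> X, h; b -> h, Y; h -> Z.  One hybridization."""
    return nr.read_enewick_network("((X,(Z)#H1),(#H1,Y));")


@pytest.fixture
def caterpillar():
    """The species tree ((X,Y),C)."""
    return nr.read_enewick_network("((X,Y),C);")


def diamond_parts(net):
    """Named nodes of the diamond fixture."""
    X = net.label_to_leaf["X"]
    Y = net.label_to_leaf["Y"]
    Z = net.label_to_leaf["Z"]
    h = net.parent(Z)
    a = net.parent(X)
    b = net.parent(Y)
    return {"r": net.root, "a": a, "b": b, "h": h, "X": X, "Y": Y, "Z": Z}


def level2_gadget(a, b, c, i):
    """Extended Newick for a level-2 blob (2 hybridizations) over three
    leaf positions; ``i`` numbers the hybrid tags."""
    return f"(({a},(({b})#H{i + 1})#H{i}),(#H{i},(#H{i + 1},{c})))"


@pytest.fixture
def stacked_level2():
    """Three level-2 blobs in series: level 2, six hybridization nodes."""
    inner2 = level2_gadget("g", "h", "i", 5)
    inner1 = level2_gadget("d", "e", inner2, 3)
    return nr.read_enewick_network(level2_gadget("a", "b", inner1, 1) + ";")


def random_instance(rng: random.Random, max_h=6, max_species=10, max_genes=10):
    """A random (gene tree, network, costs) triple for oracle comparisons."""
    h = rng.randint(0, max_h)
    n = rng.randint(3, max_species)
    net = nr.random_network(n, h, rng.randrange(2**30))
    gene = nr.random_gene_tree(
        sorted(net.species), rng.randint(2, max_genes), rng.randrange(2**30)
    )
    costs = nr.CostParams(
        rng.choice([1.0, 1.0, 2.0]), rng.choice([1.0, 1.0, 0.5])
    )
    return gene, net, costs


def random_dp_instance(rng: random.Random, max_h=4):
    """A random instance small enough for the network-reconciliation oracle
    (at most 25 network nodes and 6 internal gene nodes)."""
    h = rng.randint(0, max_h)
    n = rng.randint(3, min(9, 13 - h))
    net = nr.random_network(n, h, rng.randrange(2**30))
    gene = nr.random_gene_tree(
        sorted(net.species), rng.randint(2, 7), rng.randrange(2**30)
    )
    costs = nr.CostParams(
        rng.choice([1.0, 1.0, 2.0]), rng.choice([1.0, 1.0, 0.5])
    )
    return gene, net, costs
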