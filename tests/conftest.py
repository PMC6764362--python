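"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from phyloconflict import PhyloTree, SimulationConfig, parse_newick, simulate_reference
from phyloconflict.likelihood import _ArrTree


def exhaustive_loglik(aln, tree, model) -> float:
    """Brute-force likelihood: sum over every internal-state assignment.

    Independent of the pruning recursion; only feasible for tiny trees.
    """
    at = _ArrTree(tree, aln)
    n = len(at.nodes)
    internals = [i for i in range(n) if at.children[i]]
    total = 0.0
    for site in range(at.nsites):
        sitelik = 0.0
        for cat in range(model.n_rate_categories):
            r = model.category_rates[cat]
            Ps = {
                i: model.transition_matrix(at.lengths[i], r)
                for i in range(n)
                if i != at.root
            }
            s = 0.0
            for assign in itertools.product(range(4), repeat=len(internals)):
                st = dict(zip(internals, assign))
                pr = model.freqs[st[at.root]]
                for i in range(n):
                    if i == at.root:
                        continue
                    pstate = st[at.parent[i]]
                    if at.children[i]:
                        pr *= Ps[i][pstate, st[i]]
                    else:
                        pr *= float(Ps[i][pstate] @ at.leaf_rows[i][site])
                s += pr
            sitelik += s / model.n_rate_categories
        total += math.log(sitelik)
    return total


def random_binary_tree(rng: np.random.Generator, n_leaves: int,
                       bl_range=(0.05, 0.5)) -> PhyloTree:
    """Random unrooted-shaped binary tree with random branch lengths."""
    n_gen = max(n_leaves, 6)
    cfg = SimulationConfig(seed=int(rng.integers(2**31 - 1)), n_taxa=n_gen,
                           crown_age=float(n_gen))
    tree, _ = simulate_reference(cfg)
    if n_leaves < n_gen:
        tree = tree.prune_to(sorted(tree.leaf_labels())[:n_leaves])
    t = tree.unrooted_copy()
    for node in t.postorder():
        if node is not t.root:
            node.length = float(rng.uniform(*bl_range))
    return t


def dendropy_rf(t1: PhyloTree, t2: PhyloTree) -> int:
    """Independent RF oracle via dendropy on a shared taxon namespace."""
    import dendropy

    tns = dendropy.TaxonNamespace()
    d1 = dendropy.Tree.get(data=t1.to_newick(), schema="newick",
                           taxon_namespace=tns, preserve_underscores=True)
    d2 = dendropy.Tree.get(data=t2.to_newick(), schema="newick",
                           taxon_namespace=tns, preserve_underscores=True)
    d1.encode_bipartitions()
    d2.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(d1, d2)


@pytest.fixture
def quartet():
    return parse_newick("((A,B),(C,D));")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
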