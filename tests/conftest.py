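"""Shared fixtures: the bundled dataset, a reference optimum, cached searches."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import parsclad as pc

#: One 24-step binary resolution of the bundled matrix (used as a scoring
#: certificate; search tests re-derive it independently).
CERTIFICATE = (
    "(willistoni,(neocordata,((emarginata,(sturtevanti,(dacunhai,milleri))),"
    "(parasaltans,(saltans,(lusaltans,(prosaltans,austrosaltans)))))));"
)


@pytest.fixture(scope="session")
def saltans_matrix():
    return pc.load_bundled_matrix()


@pytest.fixture(scope="session")
def certificate_tree():
    return pc.parse_newick(CERTIFICATE)


@pytest.fixture(scope="session")
def saltans_bnb(saltans_matrix):
    """Exact search on the bundled matrix, computed once per session."""
    return pc.branch_and_bound(saltans_matrix)


def has_bipartition(tree, side) -> bool:
    """True if ``side`` (or its complement) is a split of ``tree``."""
    labels = frozenset(tree.leaf_labels())
    side = frozenset(side)
    return side in tree.splits() or (labels - side) in tree.splits()


def star_tree(labels):
    """A single-internal-node (star) tree over ``labels``."""
    from parsclad.trees import Node, PhyloTree
    return PhyloTree(Node(None, [Node(l) for l in labels]), rooted=False)


def brute_force_char_steps(tree, matrix, char_id):
    """Oracle: minimum changes of one character by enumerating every
    internal-node state assignment (independent of Fitch/Hartigan)."""
    j = char_id - 1
    col = matrix.cells[:, j]
    index = {t: i for i, t in enumerate(matrix.taxa)}
    states = sorted(int(s) for s in np.unique(col[col != pc.MISSING]))
    if len(states) <= 1:
        return 0
    internal = [n for n in tree.preorder() if not n.is_leaf]
    best = None
    for assign in itertools.product(states, repeat=len(internal)):
        a = {id(n): s for n, s in zip(internal, assign)}
        cost = 0
        for node in tree.preorder():
            if node.parent is None:
                continue
            ps = a[id(node.parent)]
            if node.is_leaf:
                s = int(col[index[node.label]])
                if s != pc.MISSING and s != ps:
                    cost += 1
            elif a[id(node)] != ps:
                cost += 1
        if best is None or cost < best:
            best = cost
    return best


def brute_force_mprs(tree, matrix, char_id):
    """Oracle: all optimal internal assignments, keyed by clade leaf sets."""
    j = char_id - 1
    col = matrix.cells[:, j]
    index = {t: i for i, t in enumerate(matrix.taxa)}
    states = sorted(int(s) for s in np.unique(col[col != pc.MISSING]))
    internal = [n for n in tree.preorder() if not n.is_leaf]
    clades = tree.clades()
    if not states:
        return 0, [dict()]
    best, mprs = None, []
    for assign in itertools.product(states, repeat=len(internal)):
        a = {id(n): s for n, s in zip(internal, assign)}
        cost = 0
        for node in tree.preorder():
            if node.parent is None:
                continue
            ps = a[id(node.parent)]
            if node.is_leaf:
                s = int(col[index[node.label]])
                if s != pc.MISSING and s != ps:
                    cost += 1
            elif a[id(node)] != ps:
                cost += 1
        if best is None or cost < best:
            best, mprs = cost, [a]
        elif cost == best:
            mprs.append(a)
    keyed = [{clades[n]: a[id(n)] for n in internal} for a in mprs]
    return best, keyed
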