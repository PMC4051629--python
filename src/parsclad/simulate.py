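"""Synthetic character matrices with known ground truth.

Three generators keep the whole pipeline testable without any external
data:

* :func:`simulate_mk` - Mk-style stochastic characters: a known topology,
  a Poisson number of state changes on each branch (branch-specific
  means), targets drawn uniformly among the other states.  Emulates
  small morphological matrices (2-3 unordered states, optionally an
  autapomorphy-rich fraction, no missing data).
* :func:`simulate_perfect_hierarchy` - one clade-membership character per
  internal edge: a fully compatible matrix whose unique most-parsimonious
  tree is the generating topology, with length = number of characters.
* :func:`permute_columns` - a null model: each column shuffled across
  taxa independently, preserving per-character state multisets (hence
  sum-of-minsteps and sum-of-maxsteps) while destroying hierarchical
  signal.

Change counts are simulated per branch rather than via continuous-time
rates: simpler, and it controls expected homoplasy directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import MatrixError, TreeError
from .matrix import CharacterMatrix
from .trees import Node, PhyloTree


@dataclass
class SimulationSpec:
    """Study conditions for one Mk-style simulated matrix.

    ``tree`` must be rooted; each non-root node's ``length`` is the
    expected (Poisson mean) number of state changes on the branch above
    it.  ``autapomorphy_fraction`` is the share of characters forced to
    vary in exactly one leaf, emulating the autapomorphy-rich matrices
    typical of species-diagnostic morphology.
    """

    tree: PhyloTree
    n_characters: int
    states_per_character: int = 2
    autapomorphy_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.states_per_character not in (2, 3):
            raise MatrixError("states_per_character must be 2 or 3")
        if not 0.0 <= self.autapomorphy_fraction <= 1.0:
            raise MatrixError("autapomorphy_fraction must be in [0, 1]")
        if self.n_characters < 1:
            raise MatrixError("n_characters must be >= 1")


# ---------------------------------------------------------------------------
# tree builders


def random_topology(labels: list[str], seed: int,
                    branch_mean: float = 0.3) -> PhyloTree:
    """A random rooted binary topology with constant per-branch change mean.

    Built by repeatedly joining two uniformly chosen subtrees, which makes
    every labelled shape reachable; deterministic given ``seed``.
    """
    if len(labels) < 3:
        raise TreeError("need at least 3 labels")
    rng = np.random.default_rng(seed)
    pool: list[Node] = [Node(l, length=branch_mean) for l in labels]
    while len(pool) > 2:
        i, j = sorted(rng.choice(len(pool), size=2, replace=False))
        b = pool.pop(int(j))
        a = pool.pop(int(i))
        pool.append(Node(None, [a, b], length=branch_mean))
    root = Node(None, pool)
    root.length = None
    return PhyloTree(root, rooted=True)


def caterpillar_tree(labels: list[str], branch_mean: float = 0.3) -> PhyloTree:
    """The fully pectinate (ladder) rooted topology over ``labels``."""
    if len(labels) < 3:
        raise TreeError("need at least 3 labels")
    node = Node(labels[0], length=branch_mean)
    for lab in labels[1:-1]:
        node = Node(None, [node, Node(lab, length=branch_mean)], length=branch_mean)
    root = Node(None, [node, Node(labels[-1], length=branch_mean)])
    root.children[0].length = branch_mean
    return PhyloTree(root, rooted=True)


# ---------------------------------------------------------------------------
# generators


def simulate_mk(spec: SimulationSpec) -> tuple[CharacterMatrix, PhyloTree]:
    """Simulate a matrix under ``spec``; returns (matrix, generating tree).

    Root state is 0; along each branch the number of changes is Poisson
    with that branch's mean and each change jumps to a state drawn
    uniformly among the other states.  Fully determined by
    ``spec`` + ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    tree = spec.tree
    leaves = tree.leaf_labels()
    n_states = spec.states_per_character
    n_auto = int(round(spec.autapomorphy_fraction * spec.n_characters))
    columns: list[dict[str, int]] = []

    for _ in range(spec.n_characters - n_auto):
        states: dict[int, int] = {id(tree.root): 0}
        for node in tree.preorder():
            if node.parent is None:
                continue
            s = states[id(node.parent)]
            mean = node.length if node.length is not None else 0.0
            for _ in range(int(rng.poisson(mean))):
                s = int((s + 1 + rng.integers(n_states - 1)) % n_states)
            states[id(node)] = s
        columns.append({n.label: states[id(n)] for n in tree.leaves()})

    for _ in range(n_auto):
        bearer = leaves[int(rng.integers(len(leaves)))]
        columns.append({l: (1 if l == bearer else 0) for l in leaves})

    cells = np.array([[columns[j][l] for j in range(spec.n_characters)]
                      for l in leaves], dtype=np.int8)
    return CharacterMatrix(taxa=list(leaves), cells=cells), tree


def simulate_perfect_hierarchy(tree: PhyloTree,
                               chars_per_internal_edge: int = 1) -> CharacterMatrix:
    """A fully compatible matrix: one 0/1 clade-membership character per
    internal edge of ``tree`` (each repeated ``chars_per_internal_edge``
    times).  The unique most-parsimonious topology is ``tree`` itself and
    its length equals the number of characters (CI = RI = 1)."""
    if chars_per_internal_edge < 1:
        raise MatrixError("chars_per_internal_edge must be >= 1")
    if not tree.is_binary():
        raise TreeError("perfect-hierarchy generation needs a binary tree")
    leaves = tree.leaf_labels()
    splits = sorted(tree.splits(), key=lambda s: (len(s), sorted(s)))
    if not splits:
        raise TreeError("tree has no internal edge")
    cols = []
    for s in splits:
        cols.extend([s] * chars_per_internal_edge)
    cells = np.array([[1 if l in s else 0 for s in cols] for l in leaves],
                     dtype=np.int8)
    return CharacterMatrix(taxa=list(leaves), cells=cells)


def permute_columns(matrix: CharacterMatrix, seed: int) -> CharacterMatrix:
    """Independently shuffle each character's states across taxa."""
    rng = np.random.default_rng(seed)
    cells = matrix.cells.copy()
    for j in range(matrix.n_characters):
        cells[:, j] = cells[rng.permutation(matrix.n_taxa), j]
    return CharacterMatrix(
        taxa=list(matrix.taxa), cells=cells,
        char_names=list(matrix.char_names), outgroup=matrix.outgroup,
    )
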