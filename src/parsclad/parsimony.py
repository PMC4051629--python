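"""Character fit on a fixed topology.

Tree length under equal-cost (unordered, "non-additive") parsimony via the
Fitch set algorithm, generalised to polytomies with Hartigan's
count-based rule; per-character step bounds (minsteps m, maxsteps g);
exact enumeration of most-parsimonious reconstructions (MPRs); and the
changes common to every MPR ("unambiguous optimization").

Missing cells enter the algorithms as the universal state set and never
force a change; m and g are computed from non-missing cells only.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .errors import CapExceededError, TreeError
from .matrix import MISSING, CharacterMatrix
from .trees import Node, PhyloTree, unroot

UNAMBIGUOUS = "unambiguous"
AMBIGUOUS = "ambiguous"


def _unrooted_view(tree: PhyloTree) -> PhyloTree:
    """Reconstructions are done on the unrooted topology: a degree-2 root
    splits one edge in two and manufactures spurious MPR ambiguity there."""
    if not tree.root.is_leaf and len(tree.root.children) == 2:
        return unroot(tree)
    return tree


@dataclass(frozen=True)
class ChangeRecord:
    """One inferred state change on one branch.

    The branch is identified by the leaf set of the clade below it (in the
    rooted view used for reconstruction).  ``classification`` is filled by
    :func:`parsclad.mapping.annotate_tree`.
    """

    char_id: int
    clade: frozenset[str]
    from_state: int
    to_state: int
    ambiguity: str = UNAMBIGUOUS
    classification: str | None = None


@dataclass(frozen=True)
class LengthResult:
    """Total and per-character parsimony steps on one topology."""

    total_steps: float
    per_character_steps: list[int]
    weighted: bool

    def __int__(self) -> int:
        return int(self.total_steps)


@dataclass(frozen=True)
class CharBounds:
    """Per-character step bounds: m (minsteps) and g (maxsteps).

    ``m_i`` = observed states - 1: the fewest changes character *i* can
    require on any tree.  ``g_i`` = non-missing taxa - largest single-state
    frequency: the star-tree length, the most changes any tree can force
    (the TNT/PAUP maxsteps convention that feeds the retention index).
    """

    per_character: list[tuple[int, int]]
    total_m: int
    total_g: int


@dataclass
class MprResult:
    """All most-parsimonious reconstructions of one character.

    ``mprs`` maps each internal node (keyed by the leaf set of its clade)
    to a state, one dict per reconstruction; ``node_state_sets`` is the
    per-node union over reconstructions.
    """

    char_id: int
    n_changes: int
    mprs: list[dict[frozenset[str], int]]
    node_state_sets: dict[frozenset[str], set[int]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# length


def _check_leaf_set(tree: PhyloTree, matrix: CharacterMatrix) -> None:
    tree_set = set(tree.leaf_labels())
    mat_set = set(matrix.taxa)
    if tree_set != mat_set:
        only_tree = sorted(tree_set - mat_set)
        only_mat = sorted(mat_set - tree_set)
        raise TreeError(
            "tree leaves and matrix taxa differ: "
            f"only in tree {only_tree}, only in matrix {only_mat}"
        )


def _char_steps(tree: PhyloTree, matrix: CharacterMatrix, j: int) -> int:
    """Minimum changes of character column ``j`` (0-based) on the topology.

    Hartigan's bottom-up rule: each node keeps the states attained by a
    maximal number of children; every child outside that majority costs
    one change.  On binary nodes this is exactly Fitch
    (intersection/union); the count is invariant to root placement because
    state costs are symmetric.
    """
    col = matrix.cells[:, j]
    index = {t: i for i, t in enumerate(matrix.taxa)}
    alphabet = frozenset(int(s) for s in np.unique(col[col != MISSING]))
    if len(alphabet) <= 1:
        return 0
    steps = 0
    sets: dict[int, frozenset[int]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            s = int(col[index[node.label]])
            sets[id(node)] = alphabet if s == MISSING else frozenset((s,))
        else:
            counts: Counter = Counter()
            for c in node.children:
                for s in sets[id(c)]:
                    counts[s] += 1
            best = max(counts.values())
            steps += len(node.children) - best
            sets[id(node)] = frozenset(s for s, k in counts.items() if k == best)
    return steps


def tree_length(tree: PhyloTree, matrix: CharacterMatrix) -> LengthResult:
    """Parsimony length of ``tree`` on ``matrix``.

    ``total_steps`` is the weight-summed length (plain sum under equal
    weights); ``per_character_steps`` are the unweighted minima.  The
    result is independent of where the tree is rooted.
    """
    _check_leaf_set(tree, matrix)
    steps = [_char_steps(tree, matrix, j) for j in range(matrix.n_characters)]
    weighted = any(w != 1 for w in matrix.weights)
    total = sum(w * s for w, s in zip(matrix.weights, steps))
    if not weighted:
        total = int(total)
    return LengthResult(total_steps=total, per_character_steps=steps,
                        weighted=weighted)


def char_bounds(matrix: CharacterMatrix) -> CharBounds:
    """Per-character (m, g) bounds plus their ensemble sums."""
    per: list[tuple[int, int]] = []
    for cid in matrix.char_ids:
        col = matrix.column(cid)
        counts = Counter(int(s) for s in col if s != MISSING)
        if not counts:
            per.append((0, 0))
            continue
        m = len(counts) - 1
        g = sum(counts.values()) - max(counts.values())
        per.append((m, g))
    return CharBounds(per_character=per,
                      total_m=sum(m for m, _ in per),
                      total_g=sum(g for _, g in per))


# ---------------------------------------------------------------------------
# MPR enumeration


def mpr_enumerate(tree: PhyloTree, matrix: CharacterMatrix, char_id: int,
                  max_mprs: int = 10 ** 6) -> MprResult:
    """Enumerate every reconstruction of one character that attains s_i.

    Depth-first assignment of internal-node states over the character's
    observed alphabet, pruned as soon as the partial cost exceeds the
    Fitch/Hartigan minimum.  Feasible throughout this package's scale
    (alphabets of 2-3 states, at most ~20 internal nodes); refuses to
    return more than ``max_mprs`` reconstructions.
    """
    _check_leaf_set(tree, matrix)
    tree = _unrooted_view(tree)
    j = char_id - 1
    if not 0 <= j < matrix.n_characters:
        raise TreeError(f"no character {char_id}")
    s_min = _char_steps(tree, matrix, j)
    col = matrix.cells[:, j]
    index = {t: i for i, t in enumerate(matrix.taxa)}
    alphabet = sorted(int(s) for s in np.unique(col[col != MISSING]))
    clades = tree.clades()
    internal = [n for n in tree.preorder() if not n.is_leaf]

    if not alphabet:
        return MprResult(char_id=char_id, n_changes=0, mprs=[{}])

    # cost contributed by the leaf children of each internal node, given its state
    leaf_cost: dict[int, dict[int, int]] = {}
    for node in internal:
        per_state = {}
        for st in alphabet:
            c = 0
            for child in node.children:
                if child.is_leaf:
                    leaf_state = int(col[index[child.label]])
                    if leaf_state != MISSING and leaf_state != st:
                        c += 1
            per_state[st] = c
        leaf_cost[id(node)] = per_state

    parent_pos = {}  # index into `internal` of each internal node's parent
    pos = {id(n): i for i, n in enumerate(internal)}
    for i, n in enumerate(internal):
        parent_pos[i] = pos[id(n.parent)] if n.parent is not None else None

    mprs: list[dict[frozenset[str], int]] = []
    assign = [0] * len(internal)

    def rec(i: int, cost: int) -> None:
        if cost > s_min:
            return
        if i == len(internal):
            if cost == s_min:
                if len(mprs) >= max_mprs:
                    raise CapExceededError(
                        f"character {char_id}: more than {max_mprs:,} MPRs"
                    )
                mprs.append({clades[n]: assign[k] for k, n in enumerate(internal)})
            return
        node = internal[i]
        pp = parent_pos[i]
        for st in alphabet:
            extra = leaf_cost[id(node)][st]
            if pp is not None and assign[pp] != st:
                extra += 1
            assign[i] = st
            rec(i + 1, cost + extra)

    rec(0, 0)
    result = MprResult(char_id=char_id, n_changes=s_min, mprs=mprs)
    for mpr in mprs:
        for clade, st in mpr.items():
            result.node_state_sets.setdefault(clade, set()).add(st)
    return result


def _mpr_changes(tree: PhyloTree, matrix: CharacterMatrix, char_id: int,
                 mpr: dict[frozenset[str], int]) -> set[tuple[frozenset[str], int, int]]:
    """The (branch, from, to) change set implied by one reconstruction."""
    tree = _unrooted_view(tree)
    j = char_id - 1
    col = matrix.cells[:, j]
    index = {t: i for i, t in enumerate(matrix.taxa)}
    clades = tree.clades()
    out: set[tuple[frozenset[str], int, int]] = set()
    for node in tree.preorder():
        if node.parent is None:
            continue
        parent_state = mpr[clades[node.parent]]
        if node.is_leaf:
            st = int(col[index[node.label]])
            if st == MISSING:
                continue
        else:
            st = mpr[clades[node]]
        if st != parent_state:
            out.add((clades[node], parent_state, st))
    return out


def unambiguous_changes(tree: PhyloTree, matrix: CharacterMatrix) -> list[ChangeRecord]:
    """All inferred changes, flagged unambiguous or ambiguous per character.

    A change is UNAMBIGUOUS iff it occurs - same branch, same states - in
    every MPR of its character; changes present in some but not all MPRs
    are returned flagged AMBIGUOUS.
    """
    tree = _unrooted_view(tree)
    records: list[ChangeRecord] = []
    for cid in matrix.char_ids:
        result = mpr_enumerate(tree, matrix, cid)
        if not result.mprs:
            continue
        change_sets = [_mpr_changes(tree, matrix, cid, mpr) for mpr in result.mprs]
        common = set.intersection(*change_sets)
        union = set.union(*change_sets)
        for clade, a, b in sorted(common, key=lambda c: (len(c[0]), sorted(c[0]), c[1], c[2])):
            records.append(ChangeRecord(cid, clade, a, b, UNAMBIGUOUS))
        for clade, a, b in sorted(union - common,
                                  key=lambda c: (len(c[0]), sorted(c[0]), c[1], c[2])):
            records.append(ChangeRecord(cid, clade, a, b, AMBIGUOUS))
    return records


def branch_min_changes(tree: PhyloTree, matrix: CharacterMatrix) -> dict[frozenset[str], int]:
    """Per branch, the minimum total change count over per-character MPRs.

    For each character independently, the branch is charged the minimum
    number of changes it carries in any MPR of that character; the sums
    are the branch "minimum lengths" used by the zero-length collapse
    rule.  Branches are keyed by the leaf set below them.
    """
    tree = _unrooted_view(tree)
    clades = tree.clades()
    totals: dict[frozenset[str], int] = {
        clades[n]: 0 for n in tree.preorder() if n.parent is not None
    }
    for cid in matrix.char_ids:
        result = mpr_enumerate(tree, matrix, cid)
        if not result.mprs:
            continue
        per_branch_min: dict[frozenset[str], int] = dict.fromkeys(totals, None)
        for mpr in result.mprs:
            changed = {clade for clade, _, _ in _mpr_changes(tree, matrix, cid, mpr)}
            for clade in per_branch_min:
                here = 1 if clade in changed else 0
                prev = per_branch_min[clade]
                per_branch_min[clade] = here if prev is None else min(prev, here)
        for clade, v in per_branch_min.items():
            totals[clade] += v or 0
    return totals
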