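"""Finding most-parsimonious trees.

Three search modes over unrooted binary topologies:

* :func:`exhaustive_search` - score every topology (the oracle; capped).
* :func:`branch_and_bound` - exact, with stepwise taxon addition, an
  admissible completion bound and a greedy initial upper bound.
* :func:`ratchet_search` - the parsimony ratchet: random-addition start,
  NNI-then-SPR hill climbing, alternating between perturbed (a random
  quarter of characters doubled in weight) and original weights.

Plus the post-processing shared by all of them: zero-minimum-length
branch collapsing, canonical deduplication and strict consensus.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from ._packed import PackedMatrix
from .errors import CapExceededError, MatrixError, TreeError
from .matrix import MISSING, CharacterMatrix
from .parsimony import branch_min_changes
from .trees import (
    Node,
    PhyloTree,
    canonical_id,
    n_unrooted_topologies,
    rep_insertions,
    rep_to_tree,
    tree_to_rep,
)


@dataclass
class SearchResult:
    """Outcome of a tree search."""

    best_length: int
    best_trees_binary: list[PhyloTree]
    best_trees_collapsed: list[PhyloTree]
    n_topologies_examined: int
    n_pruned: int
    search_log: list[dict] = field(default_factory=list)
    seed: int | None = None


# ---------------------------------------------------------------------------
# shared machinery


def _conflict_order(matrix: CharacterMatrix) -> list[int]:
    """Taxon addition order: decreasing total character conflict, then input order.

    A taxon's conflict is the number of characters in which it carries a
    non-modal state; adding conflicted taxa early tightens partial-tree
    lengths and makes branch-and-bound pruning fire sooner.
    """
    order = []
    for t in range(matrix.n_taxa):
        conflict = 0
        for j in range(matrix.n_characters):
            col = matrix.cells[:, j]
            vals = [int(s) for s in col if s != MISSING]
            if not vals:
                continue
            modal = max(set(vals), key=vals.count)
            if matrix.cells[t, j] != MISSING and matrix.cells[t, j] != modal:
                conflict += 1
        order.append((-conflict, t))
    return [t for _, t in sorted(order)]


def _completion_bonus(matrix: CharacterMatrix, order: list[int]) -> list[int]:
    """Admissible lower-bound increments for unplaced taxa.

    ``bonus[k]`` counts, summed over characters, the states present among
    the taxa not yet placed after step *k* but absent from the placed
    ones; each such state must cost at least one extra change when its
    taxa join the tree.
    """
    n = len(order)
    bonus = []
    for k in range(n + 1):
        total = 0
        for j in range(matrix.n_characters):
            placed = {int(matrix.cells[t, j]) for t in order[:k]} - {MISSING}
            unplaced = {int(matrix.cells[t, j]) for t in order[k:]} - {MISSING}
            total += len(unplaced - placed)
        bonus.append(total)
    return bonus


def _greedy_rep(packed: PackedMatrix, n: int) -> tuple[tuple, int]:
    """Stepwise addition: insert each taxon at the first cheapest branch."""
    rep = (1, 2)
    for k in range(3, n):
        best_rep, best_len = None, None
        for cand in rep_insertions(rep, k):
            l = packed.length(cand)
            if best_len is None or l < best_len:
                best_rep, best_len = cand, l
        rep = best_rep
    return rep, packed.length(rep)


def _finish(matrix: CharacterMatrix, order: list[int], best_len: int,
            optima_reps: list[tuple], examined: int, pruned: int,
            log: list[dict], seed: int | None = None) -> SearchResult:
    labels = [matrix.taxa[t] for t in order]
    trees: dict[str, PhyloTree] = {}
    for rep in optima_reps:
        t = rep_to_tree(rep, labels)
        trees.setdefault(canonical_id(t), t)
    binary = [trees[k] for k in sorted(trees)]
    collapsed = collapse_and_dedup(binary, matrix)
    log.append({"event": "done", "best_length": best_len,
                "n_binary_optima": len(binary),
                "n_collapsed_optima": len(collapsed)})
    return SearchResult(
        best_length=best_len,
        best_trees_binary=binary,
        best_trees_collapsed=collapsed,
        n_topologies_examined=examined,
        n_pruned=pruned,
        search_log=log,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# exact searches


def exhaustive_search(matrix: CharacterMatrix, cap: int = 11) -> SearchResult:
    """Score every unrooted binary topology and return all optima."""
    n = matrix.n_taxa
    if n > cap:
        raise CapExceededError(
            f"exhaustive search refused: {n} taxa means "
            f"{n_unrooted_topologies(n):,} topologies (cap {cap})"
        )
    order = list(range(n))
    packed = PackedMatrix(matrix, order)
    best: list[int | None] = [None]
    optima: list[tuple] = []
    examined = 0
    log = [{"event": "start", "mode": "exhaustive",
            "n_topologies": n_unrooted_topologies(n)}]

    def rec(rep, k: int) -> None:
        nonlocal examined
        if k == n:
            examined += 1
            l = packed.length(rep)
            if best[0] is None or l < best[0]:
                best[0] = l
                optima.clear()
                optima.append(rep)
            elif l == best[0]:
                optima.append(rep)
            return
        for r2 in rep_insertions(rep, k):
            rec(r2, k + 1)

    rec((1, 2), 3)
    return _finish(matrix, order, best[0], optima, examined, 0, log)


def branch_and_bound(matrix: CharacterMatrix,
                     initial_bound: int | None = None) -> SearchResult:
    """Exact search by stepwise addition with admissible pruning.

    Returns the same optimum length and canonical optimum set as
    :func:`exhaustive_search`.  Taxa are added in decreasing-conflict
    order; a partial tree is abandoned when its length plus the
    completion bonus for the unplaced taxa already exceeds the best
    complete tree seen.  The initial upper bound comes from one greedy
    stepwise-addition tree unless a (trusted) bound is supplied; an
    unattainably small supplied bound triggers a clean restart with the
    greedy bound.
    """
    n = matrix.n_taxa
    if n < 3:
        raise MatrixError("search needs at least 3 taxa")
    order = _conflict_order(matrix)
    packed = PackedMatrix(matrix, order)
    bonus = _completion_bonus(matrix, order)
    greedy_rep, greedy_len = _greedy_rep(packed, n)
    log: list[dict] = [{"event": "start", "mode": "branch-and-bound",
                        "addition_order": [matrix.taxa[t] for t in order]},
                       {"event": "initial_bound", "length": greedy_len,
                        "source": "greedy" if initial_bound is None else "supplied"}]
    bound = greedy_len if initial_bound is None else min(initial_bound, greedy_len)

    def run(upper: int) -> tuple[int, list[tuple], int, int]:
        best = [upper]
        optima: list[tuple] = []
        examined = pruned = 0

        def rec(rep, k: int) -> None:
            nonlocal examined, pruned
            if k == n:
                examined += 1
                l = packed.length(rep)
                if l < best[0]:
                    best[0] = l
                    optima.clear()
                    optima.append(rep)
                    log.append({"event": "new_best", "length": l})
                elif l == best[0]:
                    optima.append(rep)
                return
            for r2 in rep_insertions(rep, k):
                if packed.length(r2) + bonus[k + 1] > best[0]:
                    pruned += 1
                    continue
                rec(r2, k + 1)

        rec((1, 2), 3)
        return best[0], optima, examined, pruned

    best_len, optima, examined, pruned = run(bound)
    if not optima:  # supplied bound was below the true optimum
        log.append({"event": "bound_restart", "reason": "no tree within supplied bound"})
        best_len, optima, examined, pruned = run(greedy_len)
    return _finish(matrix, order, best_len, optima, examined, pruned, log)


# ---------------------------------------------------------------------------
# ratchet heuristic


def _prune_options(rep) -> list[tuple[object, object]]:
    """(pruned subtree, remaining rep) for every prunable position."""
    out: list[tuple[object, object]] = []

    def rec(nd, rebuild):
        for i in (0, 1):
            child, other = nd[i], nd[1 - i]
            out.append((child, rebuild(other)))
            if isinstance(child, tuple):
                rec(child, lambda x, o=other, i=i, b=rebuild: b((x, o) if i == 0 else (o, x)))

    if isinstance(rep, tuple):
        rec(rep, lambda x: x)
    return out


def _reinsert(remaining, subtree) -> list:
    if isinstance(remaining, tuple):
        return rep_insertions(remaining, subtree)
    return [(remaining, subtree)]


def _nni_neighbors(rep) -> list:
    """Both alternative resolutions of every internal edge."""
    out: list = []

    def rec(nd, rebuild):
        for i in (0, 1):
            child, other = nd[i], nd[1 - i]
            if isinstance(child, tuple):
                a, b = child
                out.append(rebuild(((a, other), b)))
                out.append(rebuild(((b, other), a)))
                rec(child, lambda x, o=other, i=i, bd=rebuild: bd((x, o) if i == 0 else (o, x)))

    if isinstance(rep, tuple):
        rec(rep, lambda x: x)
    return out


def _hill_climb(rep, packed: PackedMatrix) -> tuple[tuple, int]:
    """First-improvement hill climbing: NNI sweeps, then SPR sweeps."""
    cur = rep
    cur_len = packed.length(cur)
    while True:
        improved = False
        for nb in _nni_neighbors(cur):
            l = packed.length(nb)
            if l < cur_len:
                cur, cur_len, improved = nb, l, True
                break
        if improved:
            continue
        for subtree, remaining in _prune_options(cur):
            for nb in _reinsert(remaining, subtree):
                l = packed.length(nb)
                if l < cur_len:
                    cur, cur_len, improved = nb, l, True
                    break
            if improved:
                break
        if not improved:
            return cur, cur_len


def ratchet_search(matrix: CharacterMatrix, iterations: int = 1000,
                   seed: int | None = None) -> SearchResult:
    """Parsimony-ratchet heuristic search (deterministic given ``seed``).

    One random-addition starting tree is hill-climbed to a local optimum;
    each ratchet iteration then re-climbs under perturbed weights (a
    random ~25% of characters doubled) and again under the original
    weights, keeping every tree that ties the best length seen.
    """
    if iterations < 1:
        raise MatrixError("iterations must be >= 1")
    if seed is None:
        raise MatrixError("ratchet_search requires an explicit seed")
    n = matrix.n_taxa
    if n < 3:
        raise MatrixError("search needs at least 3 taxa")
    rng = random.Random(seed)
    order = list(range(n))
    rng.shuffle(order)
    packed = PackedMatrix(matrix, order)
    n_char = matrix.n_characters
    n_up = max(1, round(0.25 * n_char))
    log: list[dict] = [{"event": "start", "mode": "ratchet", "seed": seed,
                        "iterations": iterations,
                        "addition_order": [matrix.taxa[t] for t in order]}]

    rep, _ = _greedy_rep(packed, n)
    cur, cur_len = _hill_climb(rep, packed)
    best_len = cur_len
    best_reps: list[tuple] = [cur]
    log.append({"event": "initial_climb", "length": cur_len})
    examined = 2 * n - 5  # re-used as a coarse count of starting insertions

    for it in range(iterations):
        weights = [1] * n_char
        for j in rng.sample(range(n_char), n_up):
            weights[j] = 2
        perturbed = PackedMatrix(matrix, order, weights=weights)
        cur, _ = _hill_climb(cur, perturbed)
        cur, cur_len = _hill_climb(cur, packed)
        if cur_len < best_len:
            best_len = cur_len
            best_reps = [cur]
            log.append({"event": "new_best", "iteration": it, "length": cur_len})
        elif cur_len == best_len:
            best_reps.append(cur)

    return _finish(matrix, order, best_len, best_reps, examined, 0, log, seed=seed)


# ---------------------------------------------------------------------------
# collapsing and consensus


def collapse_and_dedup(trees: list[PhyloTree], matrix: CharacterMatrix,
                       rule: str = "min-length-zero") -> list[PhyloTree]:
    """Collapse zero-minimum-length branches, then deduplicate.

    Under rule ``min-length-zero`` an internal branch is collapsed when
    every character admits an MPR without a change on it (its minimum
    length over reconstructions is zero); tree length is unchanged by the
    operation.  Rule ``none`` only deduplicates.
    """
    if rule not in ("min-length-zero", "min-zero", "none"):
        raise MatrixError(f"unknown collapse rule {rule!r}")
    out: dict[str, PhyloTree] = {}
    for tree in trees:
        t = tree.copy()
        if rule != "none":
            bmin = branch_min_changes(t, matrix)
            clades = t.clades()
            for node in list(t.postorder()):
                if node.is_leaf or node.parent is None:
                    continue
                if bmin[clades[node]] == 0:
                    parent = node.parent
                    i = parent.children.index(node)
                    parent.children[i:i + 1] = node.children
                    for c in node.children:
                        c.parent = parent
        out.setdefault(canonical_id(t), t)
    return [out[k] for k in sorted(out)]


def strict_consensus(trees: list[PhyloTree]) -> PhyloTree:
    """The tree whose splits are exactly those present in every input tree."""
    if not trees:
        raise TreeError("strict_consensus needs at least one tree")
    leafset = set(trees[0].leaf_labels())
    for t in trees[1:]:
        if set(t.leaf_labels()) != leafset:
            raise TreeError("strict_consensus: trees are on different leaf sets")
    common = set.intersection(*(t.splits() for t in trees))
    # Build the laminar hierarchy of the common splits (each normalised to
    # the side away from the reference leaf, so they nest under the root).
    by_size = sorted(common, key=len, reverse=True)
    root = Node(None)
    nodes: dict[frozenset[str], Node] = {}
    for clade in by_size:
        # smallest strict superset among already-built clades
        candidates = [c for c in nodes if clade < c]
        parent = nodes[min(candidates, key=len)] if candidates else root
        node = Node(None)
        parent.add(node)
        nodes[clade] = node
    for leaf in sorted(leafset):
        candidates = [c for c in nodes if leaf in c]
        parent = nodes[min(candidates, key=len)] if candidates else root
        parent.add(Node(leaf))
    return PhyloTree(root, rooted=False)
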