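"""Phylogenetic tree model, newick I/O, rooting and topology enumeration.

Trees are stored as rooted node structures; an unrooted tree is represented
with a basal multifurcation and ``rooted=False``.  Parsimony treats trees
as unrooted (length is invariant under re-rooting), so rooting here is a
presentation concern: :func:`root_at_outgroup` orients an unrooted optimum
the way cladograms are conventionally drawn.
"""

from __future__ import annotations

from typing import Callable, Iterator

import dendropy

from .errors import CapExceededError, TreeError


class Node:
    """One tree node: a label (leaves), children, and branch metadata."""

    __slots__ = ("label", "children", "parent", "length", "changes")

    def __init__(self, label: str | None = None, children: list["Node"] | None = None,
                 length: float | None = None):
        self.label = label
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.length = length
        self.changes: list = []  # ChangeRecord list, filled by mapping.annotate_tree
        for c in children or []:
            self.add(c)

    def add(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:
        return f"<Node {self.label!r}>" if self.is_leaf else f"<Node {len(self.children)} children>"


class PhyloTree:
    """A rooted or unrooted tree over labelled leaves; polytomies allowed."""

    def __init__(self, root: Node, rooted: bool = True):
        self.root = root
        self.rooted = rooted
        labels = self.leaf_labels()
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate leaf label(s): {', '.join(dup)}")
        if any(not l for l in labels):
            raise TreeError("empty leaf label")

    # -- traversal ------------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, seen = stack.pop()
            if seen or node.is_leaf:
                yield node
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def is_binary(self) -> bool:
        """True if every internal node of the *unrooted* view has degree 3."""
        for node in self.postorder():
            if node.is_leaf:
                continue
            k = len(node.children)
            if node is self.root:
                want = (2,) if self.rooted else (3,)
                if k not in want:
                    return False
            elif k != 2:
                return False
        return True

    def copy(self) -> "PhyloTree":
        def rec(n: Node) -> Node:
            m = Node(n.label, [rec(c) for c in n.children], n.length)
            m.changes = list(n.changes)
            return m
        return PhyloTree(rec(self.root), rooted=self.rooted)

    def clades(self) -> dict[Node, frozenset[str]]:
        """Leaf-label set under every node (rooted view)."""
        out: dict[Node, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                out[node] = frozenset([node.label])
            else:
                s: frozenset[str] = frozenset()
                for c in node.children:
                    s |= out[c]
                out[node] = s
        return out

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions of the underlying unrooted topology.

        Each split is normalised as the side *not* containing the
        lexicographically smallest leaf.
        """
        labels = set(self.leaf_labels())
        ref = min(labels)
        n = len(labels)
        clades = self.clades()
        out: set[frozenset[str]] = set()
        for node, side in clades.items():
            if node is self.root:
                continue
            if ref in side:
                side = frozenset(labels - side)
            if 2 <= len(side) <= n - 2:
                out.add(side)
        return out

    def __repr__(self) -> str:
        kind = "rooted" if self.rooted else "unrooted"
        return f"<PhyloTree {kind}, {self.n_leaves} leaves>"


# ---------------------------------------------------------------------------
# newick I/O (dendropy-backed parsing)


def _check_balanced(text: str) -> None:
    depth = 0
    for offset, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise TreeError(f"unbalanced ')' at character offset {offset}")
    if depth != 0:
        raise TreeError(
            f"unbalanced newick: {depth} unclosed '(' at end of text "
            f"(length {len(text)})"
        )


def parse_newick(text: str) -> PhyloTree:
    """Parse a single newick tree.

    Branch lengths, if present, are preserved on the nodes but ignored by
    every parsimony computation.  A root with exactly two children is
    reported as rooted; a basal multifurcation as unrooted.
    """
    if not text or not text.strip():
        raise TreeError("empty newick text")
    _check_balanced(text)
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise TreeError(f"newick parse failure: {exc}") from None

    def rec(dnode) -> Node:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon else dnode.label
            if not label:
                raise TreeError("leaf without a label")
            return Node(label, length=dnode.edge.length)
        node = Node(dnode.label or None,
                    [rec(c) for c in dnode.child_nodes()],
                    length=dnode.edge.length)
        return node

    root = rec(dtree.seed_node)
    if len(root.children) < 2:
        # degree-1 seed (e.g. "((A,B),C);" wrapped oddly) - flatten
        while len(root.children) == 1:
            root = root.children[0]
            root.parent = None
    return PhyloTree(root, rooted=len(root.children) == 2)


def _quote(label: str) -> str:
    if any(c in label for c in "(),:;'\" \t[]"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: PhyloTree, branch_lengths: bool = False) -> str:
    """Render a tree as newick.

    Branch lengths are omitted unless explicitly requested (the package
    produces cladograms; lengths only carry inferred change counts when a
    caller has set them deliberately).
    """
    def rec(n: Node) -> str:
        if n.is_leaf:
            s = _quote(n.label)
        else:
            s = "(" + ",".join(rec(c) for c in n.children) + ")"
        if branch_lengths and n.length is not None:
            s += f":{n.length:g}"
        return s
    return rec(tree.root) + ";"


# ---------------------------------------------------------------------------
# rooting


def _adjacency(tree: PhyloTree) -> tuple[dict[int, list[tuple[Node, float | None]]], dict[int, Node]]:
    """Undirected adjacency of the tree with any degree-2 root suppressed."""
    adj: dict[int, list[tuple[Node, float | None]]] = {}
    nodes: dict[int, Node] = {}

    def add_edge(a: Node, b: Node, length: float | None) -> None:
        adj.setdefault(id(a), []).append((b, length))
        adj.setdefault(id(b), []).append((a, length))
        nodes[id(a)] = a
        nodes[id(b)] = b

    for node in tree.postorder():
        for c in node.children:
            add_edge(node, c, c.length)
    root = tree.root
    if len(root.children) == 2 and not root.is_leaf:
        a, b = root.children
        la = a.length or 0.0
        lb = b.length or 0.0
        joint = (la + lb) if (a.length is not None or b.length is not None) else None
        adj[id(a)] = [(x, l) for x, l in adj[id(a)] if x is not root] + [(b, joint)]
        adj[id(b)] = [(x, l) for x, l in adj[id(b)] if x is not root] + [(a, joint)]
        del adj[id(root)]
        nodes.pop(id(root), None)
    return adj, nodes


def root_at_outgroup(tree: PhyloTree, outgroup: str) -> PhyloTree:
    """Root a tree so that its root has two children: the outgroup leaf and
    the ingroup subtree.  The underlying unrooted topology is unchanged."""
    leaves = {n.label: n for n in tree.leaves()}
    if outgroup not in leaves:
        raise TreeError(f"outgroup {outgroup!r} is not a leaf of the tree")
    adj, _ = _adjacency(tree)
    og = leaves[outgroup]
    nbrs = adj[id(og)]
    if len(nbrs) != 1:
        raise TreeError("outgroup must be a leaf")
    nbr, og_len = nbrs[0]

    def rebuild(node: Node, parent: Node, length: float | None) -> Node:
        if not adj.get(id(node)) or all(x is parent for x, _ in adj[id(node)]):
            return Node(node.label, length=length)
        kids = [rebuild(x, node, l) for x, l in adj[id(node)] if x is not parent]
        if not kids:
            return Node(node.label, length=length)
        return Node(node.label if node.is_leaf else None, kids, length=length)

    root = Node(None, [Node(outgroup, length=og_len), rebuild(nbr, og, None)])
    return PhyloTree(root, rooted=True)


def unroot(tree: PhyloTree) -> PhyloTree:
    """Return the unrooted view (suppress a degree-2 root)."""
    t = tree.copy()
    root = t.root
    if len(root.children) == 2:
        a, b = root.children
        if not a.is_leaf:
            inner, other = a, b
        elif not b.is_leaf:
            inner, other = b, a
        else:
            raise TreeError("cannot unroot a two-leaf tree")
        new_root = Node(None, inner.children + [other])
        return PhyloTree(new_root, rooted=False)
    t.rooted = False
    return t


# ---------------------------------------------------------------------------
# canonical identity


def canonical_id(tree: PhyloTree) -> str:
    """A token identifying the unrooted topology (label-set aware).

    Two trees map to the same token iff they are the same unrooted
    topology.  Computed as the sorted nested-parenthesis normal form after
    rooting at the lexicographically smallest leaf.
    """
    adj, _ = _adjacency(tree)
    leaves = {n.label: n for n in tree.leaves()}
    if len(leaves) < 2:
        raise TreeError("canonical_id needs at least 2 leaves")
    base_label = min(leaves)
    base = leaves[base_label]

    def rec(node: Node, parent: Node) -> str:
        kids = [x for x, _ in adj[id(node)] if x is not parent]
        if not kids:
            return node.label
        return "(" + ",".join(sorted(rec(k, node) for k in kids)) + ")"

    (nbr, _), = adj[id(base)]
    return f"({base_label},{rec(nbr, base)})"


# ---------------------------------------------------------------------------
# topology enumeration (nested-tuple machinery shared with the search module)

Rep = tuple  # nested binary tuples of taxon indices 1..n-1; index 0 is the base leaf


def rep_insertions(rep, new_leaf: int) -> list:
    """All single-edge insertions of ``new_leaf`` into a rep (one per edge)."""
    out = [(rep, new_leaf)]  # the edge leading to the base leaf

    def rec(nd, build: Callable):
        for i in (0, 1):
            child, other = nd[i], nd[1 - i]
            def mk(x, o=other, i=i, build=build):
                return build((x, o) if i == 0 else (o, x))
            out.append(mk((child, new_leaf)))
            if isinstance(child, tuple):
                rec(child, mk)

    rec(rep, lambda x: x)
    return out


def rep_to_tree(rep, labels: list[str]) -> PhyloTree:
    """Convert a nested-tuple rep (base leaf = ``labels[0]``) to an unrooted tree."""
    def build(nd) -> Node:
        if isinstance(nd, int):
            return Node(labels[nd])
        return Node(None, [build(nd[0]), build(nd[1])])
    if not isinstance(rep, tuple):
        raise TreeError("rep must be a tuple over at least 3 taxa")
    root = Node(None, [Node(labels[0]), build(rep[0]), build(rep[1])])
    return PhyloTree(root, rooted=False)


def tree_to_rep(tree: PhyloTree, labels: list[str]):
    """Convert an unrooted binary tree to its nested-tuple rep.

    ``labels`` fixes the index mapping; ``labels[0]`` becomes the base leaf.
    """
    index = {lab: i for i, lab in enumerate(labels)}
    got = set(tree.leaf_labels())
    if got != set(labels):
        missing = sorted(set(labels) - got)
        extra = sorted(got - set(labels))
        raise TreeError(f"leaf/label mismatch: missing {missing}, extra {extra}")
    adj, _ = _adjacency(tree)
    leaves = {n.label: n for n in tree.leaves()}
    base = leaves[labels[0]]

    def rec(node: Node, parent: Node):
        kids = [x for x, _ in adj[id(node)] if x is not parent]
        if not kids:
            return index[node.label]
        if len(kids) != 2:
            raise TreeError("tree is not binary (polytomy encountered)")
        return (rec(kids[0], node), rec(kids[1], node))

    (nbr, _), = adj[id(base)]
    rep = rec(nbr, base)
    if not isinstance(rep, tuple):
        raise TreeError("tree has fewer than 3 leaves")
    return rep


def n_unrooted_topologies(n: int) -> int:
    """(2n-5)!! - the number of unrooted binary topologies on n labelled leaves."""
    if n < 3:
        raise TreeError("need at least 3 leaves")
    out = 1
    for k in range(3, 2 * n - 4, 2):
        out *= k
    return out


def enumerate_topologies(taxa: list[str], cap: int = 11) -> Iterator[PhyloTree]:
    """Yield every unrooted binary topology on ``taxa`` exactly once.

    Deterministic order: stepwise insertion of taxon ``k`` into each branch
    of each partial tree, branches scanned base-edge first then preorder.
    Refuses more than ``cap`` taxa ((2n-5)!! grows too fast to stream past
    11 in reasonable time).
    """
    n = len(taxa)
    if n < 3:
        raise TreeError("need at least 3 taxa")
    if len(set(taxa)) != n:
        raise TreeError("duplicate taxon labels")
    if n > cap:
        raise CapExceededError(
            f"enumerate_topologies refused: {n} taxa would stream "
            f"{n_unrooted_topologies(n):,} topologies (cap {cap}); "
            "use branch_and_bound instead"
        )

    def rec(rep, k: int) -> Iterator:
        if k == n:
            yield rep
            return
        for r2 in rep_insertions(rep, k):
            yield from rec(r2, k + 1)

    for rep in rec((1, 2), 3):
        yield rep_to_tree(rep, taxa)
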