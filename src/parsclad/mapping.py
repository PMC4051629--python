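"""Character-change mapping and verbal topology claims.

Dresses an optimal cladogram the way published parsimony figures are
drawn: every unambiguous state change is attached to its branch and
classified as a synapomorphy (shared derived state uniting a clade), an
autapomorphy (derived state private to one terminal) or a homoplasy (any
change of a character needing more steps than its minimum on this tree).
Classification is at character level - a character whose steps s equal
its minimum m contributes synapomorphies/autapomorphies, an excess-step
character contributes homoplasies - which reproduces the black/white
circle dichotomy of standard cladogram artwork without reading artwork.

The module also checks verbal topology claims ("X and Y are sister
taxa", "Z is the most basal lineage", ...) against a rooted tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .errors import TreeError
from .matrix import CharacterMatrix
from .parsimony import (
    UNAMBIGUOUS,
    ChangeRecord,
    char_bounds,
    tree_length,
    unambiguous_changes,
)
from .trees import PhyloTree, root_at_outgroup

SYNAPOMORPHY = "synapomorphy"
AUTAPOMORPHY = "autapomorphy"
HOMOPLASY = "homoplasy"


@dataclass(frozen=True)
class TopologyStatement:
    """One machine-checkable claim about a rooted topology.

    kinds:
      ``most-basal-lineage`` (operands: the basal taxon set),
      ``sister-taxa`` (two taxa),
      ``sister-clades`` (two taxon sets),
      ``closer-than`` (three taxa a, b, c: a,b closer to each other than to c).
    """

    kind: str
    operands: tuple

    def __post_init__(self):
        kinds = {"most-basal-lineage", "sister-taxa", "sister-clades", "closer-than"}
        if self.kind not in kinds:
            raise TreeError(f"unknown statement kind {self.kind!r}")


#: The four verbal claims published for the saltans-group cladogram.
SALTANS_CLAIMS: list[TopologyStatement] = [
    TopologyStatement("most-basal-lineage", (frozenset({"neocordata"}),)),
    TopologyStatement("sister-taxa", ("dacunhai", "milleri")),
    TopologyStatement("sister-clades", (
        frozenset({"parasaltans"}),
        frozenset({"saltans", "lusaltans", "prosaltans", "austrosaltans"}),
    )),
    TopologyStatement("closer-than", ("prosaltans", "austrosaltans", "saltans")),
]


# ---------------------------------------------------------------------------
# change annotation


def classify_changes(tree: PhyloTree, matrix: CharacterMatrix) -> list[ChangeRecord]:
    """All inferred changes with their classification filled in."""
    bounds = char_bounds(matrix)
    steps = tree_length(tree, matrix).per_character_steps
    records = unambiguous_changes(tree, matrix)
    out = []
    for rec in records:
        j = rec.char_id - 1
        s, m = steps[j], bounds.per_character[j][0]
        if s > m:
            cls = HOMOPLASY
        elif len(rec.clade) == 1 and _state_frequency(matrix, rec.char_id, rec.to_state) == 1:
            cls = AUTAPOMORPHY
        elif len(rec.clade) >= 2:
            cls = SYNAPOMORPHY
        else:
            cls = AUTAPOMORPHY
        out.append(ChangeRecord(rec.char_id, rec.clade, rec.from_state,
                                rec.to_state, rec.ambiguity, cls))
    return out


def _state_frequency(matrix: CharacterMatrix, char_id: int, state: int) -> int:
    col = matrix.column(char_id)
    return int((col == state).sum())


def annotate_tree(tree: PhyloTree, matrix: CharacterMatrix) -> PhyloTree:
    """Attach every unambiguous classified change to its branch.

    Returns a copy of ``tree`` whose nodes carry the :class:`ChangeRecord`
    list of the branch above them.  Ambiguous changes are deliberately
    excluded from the branch annotation (unambiguous optimization); use
    :func:`classify_changes` to see them too.
    """
    annotated = tree.copy()
    records = [r for r in classify_changes(annotated, matrix)
               if r.ambiguity == UNAMBIGUOUS]
    clades = annotated.clades()
    by_clade: dict[frozenset, list[ChangeRecord]] = {}
    for r in records:
        by_clade.setdefault(r.clade, []).append(r)
    for node in annotated.preorder():
        node.changes = by_clade.get(clades[node], []) if node.parent is not None else []
    return annotated


def write_annotated_newick(tree: PhyloTree) -> str:
    """Newick with ``[&changes=charid:from>to,...]`` branch comments."""
    def rec(n) -> str:
        if n.is_leaf:
            s = n.label
        else:
            s = "(" + ",".join(rec(c) for c in n.children) + ")"
        if n.changes:
            items = ",".join(f"{r.char_id}:{r.from_state}>{r.to_state}"
                             for r in sorted(n.changes, key=lambda r: r.char_id))
            s += f"[&changes={items}]"
        return s
    return rec(tree.root) + ";"


def change_table_tsv(records: Sequence[ChangeRecord]) -> str:
    """Tab-separated change table (one row per inferred change)."""
    lines = ["char\tclade\tfrom\tto\tambiguity\tclassification"]
    for r in records:
        clade = "+".join(sorted(r.clade))
        lines.append(f"{r.char_id}\t{clade}\t{r.from_state}\t{r.to_state}"
                     f"\t{r.ambiguity}\t{r.classification or ''}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# verbal topology claims


def check_topology_statements(tree: PhyloTree, statements: Sequence[TopologyStatement],
                              outgroup: str) -> list[bool]:
    """Evaluate each statement on ``tree`` rooted at ``outgroup``."""
    rooted = root_at_outgroup(tree, outgroup)
    leaves = set(rooted.leaf_labels())
    ingroup = leaves - {outgroup}
    clades = set(rooted.clades().values())

    def is_clade(s: frozenset) -> bool:
        return len(s) == 1 or s in clades

    def smallest_containing(labels: set[str]) -> frozenset:
        return min((c for c in clades if labels <= c), key=len)

    results = []
    for st in statements:
        ops = st.operands
        for item in ops:
            names = item if isinstance(item, (set, frozenset)) else {item}
            unknown = set(names) - leaves
            if unknown:
                raise TreeError(f"unknown taxon label(s) {sorted(unknown)}")
        if st.kind == "most-basal-lineage":
            (x,) = ops
            x = frozenset(x) if isinstance(x, (set, frozenset)) else frozenset({x})
            rest = frozenset(ingroup - x)
            results.append(x <= ingroup and bool(rest)
                           and is_clade(x) and is_clade(rest))
        elif st.kind == "sister-taxa":
            a, b = ops
            results.append(frozenset({a, b}) in clades)
        elif st.kind == "sister-clades":
            a, b = (frozenset(o) if isinstance(o, (set, frozenset)) else frozenset({o})
                    for o in ops)
            if a & b:
                raise TreeError("sister-clades operands overlap")
            results.append(is_clade(a) and is_clade(b) and is_clade(a | b))
        else:  # closer-than
            a, b, c = ops
            if c in (a, b) or a == b:
                raise TreeError("closer-than operands must be three distinct taxa")
            results.append(c not in smallest_containing({a, b}))
    return results
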