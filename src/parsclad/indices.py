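"""Ensemble and per-character parsimony fit statistics.

Consistency index CI = M/L, retention index RI = (G-L)/(G-M), homoplasy
index HI = 1-CI and rescaled consistency RC = CI*RI, where L is tree
length, M = sum of per-character minsteps and G = sum of maxsteps.
Uninformative characters are included in the ensemble sums (the TNT
default).  The "printed" integer renderings are floor-truncations of the
percentages - 87.5 prints as 87, 90.625 as 90 - computed in exact integer
arithmetic; truncation rather than rounding is the convention that
reproduces published values of this kind from a single optimum.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import MatrixError
from .matrix import CharacterMatrix, summarize
from .parsimony import char_bounds, tree_length
from .trees import PhyloTree


@dataclass(frozen=True)
class IndexReport:
    """Per-character and ensemble fit indices for one tree."""

    # per character (aligned with char_ids): m, g, s, ci (None when s=0),
    # ri (None when g=m)
    per_character: list[dict]
    L: int
    M: int
    G: int
    CI: float
    RI: float
    HI: float
    RC: float
    printed_CI: int
    printed_RI: int

    def rows(self) -> list[tuple]:
        """(char_id, m, g, s, ci, ri) tuples for tabular output."""
        return [
            (row["char_id"], row["m"], row["g"], row["s"], row["ci"], row["ri"])
            for row in self.per_character
        ]


def index_report(matrix: CharacterMatrix, tree: PhyloTree,
                 include_uninformative: bool = True) -> IndexReport:
    """Compute CI/RI/HI/RC (ensemble and per character) of ``tree``.

    By default every character enters the ensemble sums, the convention
    that published CI/RI values of this kind follow; pass
    ``include_uninformative=False`` to restrict L, M and G to
    parsimony-informative characters (the per-character table always
    covers all of them).  Raises if the matrix has no variable character
    (CI is undefined when M = 0).
    """
    bounds = char_bounds(matrix)
    if bounds.total_m == 0:
        raise MatrixError("all characters are constant; CI is undefined")
    length = tree_length(tree, matrix)
    steps = length.per_character_steps
    if include_uninformative:
        kept = set(matrix.char_ids)
    else:
        kept = set(summarize(matrix).informative)
        if not kept:
            raise MatrixError("no parsimony-informative characters")
    L = int(sum(s for cid, s in zip(matrix.char_ids, steps) if cid in kept))
    M = sum(m for cid, (m, _) in zip(matrix.char_ids, bounds.per_character)
            if cid in kept)
    G = sum(g for cid, (_, g) in zip(matrix.char_ids, bounds.per_character)
            if cid in kept)
    per = []
    for cid, (m, g), s in zip(matrix.char_ids, bounds.per_character, steps):
        per.append({
            "char_id": cid,
            "m": m,
            "g": g,
            "s": s,
            "ci": (m / s) if s > 0 else None,
            "ri": ((g - s) / (g - m)) if g > m else None,
        })
    CI = M / L
    RI = (G - L) / (G - M) if G > M else 1.0
    return IndexReport(
        per_character=per,
        L=L, M=M, G=G,
        CI=CI,
        RI=RI,
        HI=1.0 - CI,
        RC=CI * RI,
        printed_CI=(100 * M) // L,
        printed_RI=((100 * (G - L)) // (G - M)) if G > M else 100,
    )


def per_character_tsv(report: IndexReport) -> str:
    """Tab-separated per-character table (m, g, s, ci, ri)."""
    lines = ["char\tm\tg\ts\tci\tri"]
    for cid, m, g, s, ci, ri in report.rows():
        fmt = lambda v: "NA" if v is None else f"{v:.4f}"
        lines.append(f"{cid}\t{m}\t{g}\t{s}\t{fmt(ci)}\t{fmt(ri)}")
    return "\n".join(lines) + "\n"


def ensemble_dict(report: IndexReport) -> dict:
    """Ensemble values as a JSON-ready dict."""
    return {
        "L": report.L, "M": report.M, "G": report.G,
        "CI": report.CI, "RI": report.RI, "HI": report.HI, "RC": report.RC,
        "printed_CI": report.printed_CI, "printed_RI": report.printed_RI,
    }
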