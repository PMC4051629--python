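"""Discrete morphological character matrices.

Parsing, validation, writing and summary statistics for small taxa x
characters matrices of unordered discrete states (integer codes 0-9,
missing data ``?``), the standard input of equal-weights cladistic
analysis.  Three text dialects are supported:

``csv`` / ``tsv``
    One taxon per row: label, then one state per column.  An optional
    header row starting with the sentinel ``#taxon`` carries character
    names.
``tnt``
    A TNT-like block: ``xread 'title' nchar ntax`` followed by
    ``label statestring`` rows and a terminating ``;``.
``nexus``
    A minimal ``#NEXUS`` file with a CHARACTERS (or DATA) block
    (DIMENSIONS, FORMAT SYMBOLS="0123456789" MISSING=?, MATRIX).

The bundled example dataset is the published character matrix of the
*Drosophila saltans* species group: 19 structures of the male terminalia
and aedeagus scored in 10 saltans-group species plus the *D. willistoni*
outgroup (see ``data/README.txt``).
"""

from __future__ import annotations

import csv
import io
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources

import dendropy
import numpy as np

from .errors import MatrixError

#: Internal code for a missing ("?") cell.
MISSING: int = -1

#: Symbols accepted as states.
STATE_SYMBOLS = "0123456789"

_DIALECT_ALIASES = {
    "csv": "csv",
    "tsv": "tsv",
    "tnt": "tnt",
    "tnt-like": "tnt",
    "xread": "tnt",
    "nexus": "nexus",
    "nexus-characters": "nexus",
}

#: One most-parsimonious binary resolution (24 steps) of the bundled
#: saltans-group matrix, reproducible with :func:`parsclad.search.branch_and_bound`.
#: Kept here so examples and reports can score it without re-searching.
SALTANS_OPTIMAL_TREE_NEWICK = (
    "(willistoni,(neocordata,((emarginata,(sturtevanti,(dacunhai,milleri))),"
    "(parasaltans,(saltans,(lusaltans,(prosaltans,austrosaltans)))))));"
)


@dataclass
class CharacterMatrix:
    """A taxa x characters grid of unordered discrete states.

    Parameters
    ----------
    taxa:
        Ordered taxon labels (rows).
    cells:
        ``(n_taxa, n_characters)`` integer array; states ``0..9`` or
        :data:`MISSING` for ``?``.
    char_ids:
        1-based character numbers (always ``1..n_characters``).
    char_names:
        Free-text name per character.
    char_type:
        Per character, ``"unordered"`` (the only type exercised here;
        ``"ordered"`` is reserved).
    weights:
        Per-character positive weight, default 1 (the analyses in this
        package are equal-weights; non-unit weights only arise inside the
        ratchet's perturbation phase).
    outgroup:
        Optional label of the outgroup taxon.
    """

    taxa: list[str]
    cells: np.ndarray
    char_ids: list[int] = field(default_factory=list)
    char_names: list[str] = field(default_factory=list)
    char_type: list[str] = field(default_factory=list)
    weights: list[float] = field(default_factory=list)
    outgroup: str | None = None

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int8)
        if self.cells.ndim != 2:
            raise MatrixError("cells must be a 2-D taxa x characters grid")
        n_taxa, n_char = self.cells.shape
        if len(self.taxa) != n_taxa:
            raise MatrixError(
                f"{len(self.taxa)} taxon labels for {n_taxa} rows"
            )
        if n_taxa < 3:
            raise MatrixError("a character matrix needs at least 3 taxa")
        if n_char < 1:
            raise MatrixError("a character matrix needs at least 1 character")
        if len(set(self.taxa)) != n_taxa:
            dup = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise MatrixError(f"duplicate taxon label(s): {', '.join(dup)}")
        bad = (self.cells != MISSING) & ((self.cells < 0) | (self.cells > 9))
        if bad.any():
            r, c = map(int, np.argwhere(bad)[0])
            raise MatrixError(
                f"state {int(self.cells[r, c])} out of range 0-9 "
                f"(taxon {self.taxa[r]!r}, character {c + 1})"
            )
        if not self.char_ids:
            self.char_ids = list(range(1, n_char + 1))
        if self.char_ids != list(range(1, n_char + 1)):
            raise MatrixError("char_ids must be contiguous from 1")
        if not self.char_names:
            self.char_names = [f"char{i}" for i in self.char_ids]
        if not self.char_type:
            self.char_type = ["unordered"] * n_char
        if not self.weights:
            self.weights = [1.0] * n_char
        if any(w <= 0 for w in self.weights):
            raise MatrixError("character weights must be positive")
        for name, seq in (
            ("char_names", self.char_names),
            ("char_type", self.char_type),
            ("weights", self.weights),
        ):
            if len(seq) != n_char:
                raise MatrixError(f"{name} has wrong length")
        if self.outgroup is not None and self.outgroup not in self.taxa:
            raise MatrixError(f"outgroup {self.outgroup!r} is not a taxon")

    # -- basic accessors ------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return self.cells.shape[1]

    def column(self, char_id: int) -> np.ndarray:
        """States of one character (1-based id), in taxon order."""
        if not 1 <= char_id <= self.n_characters:
            raise MatrixError(f"no character {char_id}")
        return self.cells[:, char_id - 1]

    def row(self, taxon: str) -> np.ndarray:
        """States of one taxon, in character order."""
        try:
            return self.cells[self.taxa.index(taxon)]
        except ValueError:
            raise MatrixError(f"no taxon {taxon!r}") from None

    def observed_states(self, char_id: int) -> list[int]:
        """Sorted distinct non-missing states of one character."""
        col = self.column(char_id)
        return sorted(int(s) for s in np.unique(col[col != MISSING]))

    def __eq__(self, other: object) -> bool:
        # Data-level equality: taxa and the state grid.  Metadata that not
        # every dialect can carry (names, outgroup, weights) is excluded so
        # that write -> parse round-trips compare equal in all dialects.
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return self.taxa == other.taxa and np.array_equal(self.cells, other.cells)

    def __repr__(self) -> str:
        return (
            f"<CharacterMatrix {self.n_taxa} taxa x {self.n_characters} "
            f"characters, outgroup={self.outgroup!r}>"
        )


@dataclass(frozen=True)
class MatrixSummary:
    """Per-character census of a :class:`CharacterMatrix`."""

    n_taxa: int
    n_characters: int
    n_ingroup: int
    state_counts: list[Counter]  # per character, non-missing state -> frequency
    constant: list[int]          # 1-based ids
    autapomorphic: list[int]
    informative: list[int]

    @property
    def n_constant(self) -> int:
        return len(self.constant)

    @property
    def n_autapomorphic(self) -> int:
        return len(self.autapomorphic)

    @property
    def n_informative(self) -> int:
        return len(self.informative)


# ---------------------------------------------------------------------------
# parsing


def parse_matrix(source: str, dialect: str) -> CharacterMatrix:
    """Parse a character matrix from text.

    ``dialect`` must be declared explicitly (no sniffing): one of ``csv``,
    ``tsv``, ``tnt`` (alias ``tnt-like``) or ``nexus`` (alias
    ``nexus-characters``).  ``?`` denotes missing data; ``-`` is rejected
    because gap semantics are undefined for morphology.
    """
    if not source or not source.strip():
        raise MatrixError("empty matrix source")
    try:
        kind = _DIALECT_ALIASES[dialect.lower()]
    except KeyError:
        raise MatrixError(
            f"unknown dialect {dialect!r}; expected one of "
            f"{sorted(set(_DIALECT_ALIASES))}"
        ) from None
    if kind in ("csv", "tsv"):
        return _parse_delimited(source, "\t" if kind == "tsv" else ",")
    if kind == "tnt":
        return _parse_tnt(source)
    return _parse_nexus(source)


def _state_code(symbol: str, taxon: str, char_no: int) -> int:
    if symbol == "?":
        return MISSING
    if symbol == "-":
        raise MatrixError(
            f"gap symbol '-' is not supported for morphological data "
            f"(taxon {taxon!r}, character {char_no})"
        )
    if len(symbol) == 1 and symbol in STATE_SYMBOLS:
        return int(symbol)
    raise MatrixError(
        f"unknown state symbol {symbol!r} (taxon {taxon!r}, character {char_no})"
    )


def _parse_delimited(source: str, delim: str) -> CharacterMatrix:
    rows = [r for r in csv.reader(io.StringIO(source), delimiter=delim)
            if r and any(f.strip() for f in r)]
    char_names: list[str] = []
    if rows and rows[0][0].strip() == "#taxon":
        char_names = [f.strip() for f in rows[0][1:]]
        rows = rows[1:]
    if not rows:
        raise MatrixError("no data rows")
    n_char = len(char_names) or len(rows[0]) - 1
    taxa: list[str] = []
    cells: list[list[int]] = []
    for r in rows:
        taxon = r[0].strip()
        states = [f.strip() for f in r[1:]]
        if len(states) != n_char:
            raise MatrixError(
                f"ragged row for taxon {taxon!r}: {len(states)} states, "
                f"expected {n_char}"
            )
        taxa.append(taxon)
        cells.append([_state_code(s, taxon, j + 1) for j, s in enumerate(states)])
    return CharacterMatrix(taxa=taxa, cells=np.array(cells, dtype=np.int8),
                           char_names=char_names or [])


def _parse_tnt(source: str) -> CharacterMatrix:
    text = source.strip()
    if not text.lower().startswith("xread"):
        raise MatrixError("TNT-like block must start with 'xread'")
    body = text[len("xread"):].strip()
    # optional quoted title
    if body.startswith("'"):
        end = body.find("'", 1)
        if end < 0:
            raise MatrixError("unterminated title quote in xread block")
        body = body[end + 1:].strip()
    tokens = body.split()
    if len(tokens) < 2:
        raise MatrixError("xread header needs 'nchar ntax'")
    try:
        n_char, n_taxa = int(tokens[0]), int(tokens[1])
    except ValueError:
        raise MatrixError("xread header needs integer 'nchar ntax'") from None
    rest = body.split(None, 2)[2] if len(tokens) > 2 else ""
    if ";" not in rest:
        raise MatrixError("xread block is not terminated by ';'")
    rest = rest[: rest.index(";")]
    taxa: list[str] = []
    cells: list[list[int]] = []
    for line in rest.splitlines():
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise MatrixError(f"expected 'label statestring', got {line!r}")
        taxon, states = parts
        if len(states) != n_char:
            raise MatrixError(
                f"ragged row for taxon {taxon!r}: {len(states)} states, "
                f"expected {n_char}"
            )
        taxa.append(taxon)
        cells.append([_state_code(s, taxon, j + 1) for j, s in enumerate(states)])
    if len(taxa) != n_taxa:
        raise MatrixError(f"xread declared {n_taxa} taxa but {len(taxa)} rows found")
    return CharacterMatrix(taxa=taxa, cells=np.array(cells, dtype=np.int8))


def _parse_nexus(source: str) -> CharacterMatrix:
    try:
        dm = dendropy.StandardCharacterMatrix.get(data=source, schema="nexus")
    except Exception as exc:  # dendropy raises several error types
        raise MatrixError(f"NEXUS parse failure: {exc}") from None
    taxa: list[str] = []
    cells: list[list[int]] = []
    for tx in dm:
        taxon = tx.label
        symbols = [str(s) for s in dm[tx]]
        taxa.append(taxon)
        cells.append([_state_code(s, taxon, j + 1) for j, s in enumerate(symbols)])
    if not taxa:
        raise MatrixError("NEXUS file contains no characters matrix")
    widths = {len(r) for r in cells}
    if len(widths) != 1:
        raise MatrixError("NEXUS matrix has ragged rows")
    return CharacterMatrix(taxa=taxa, cells=np.array(cells, dtype=np.int8))


# ---------------------------------------------------------------------------
# writing


def write_matrix(matrix: CharacterMatrix, dialect: str) -> str:
    """Render a matrix in one of the supported dialects (inverse of parse)."""
    kind = _DIALECT_ALIASES.get(dialect.lower())
    if kind is None:
        raise MatrixError(f"unknown dialect {dialect!r}")
    if kind in ("csv", "tsv"):
        delim = "\t" if kind == "tsv" else ","
        out = io.StringIO()
        w = csv.writer(out, delimiter=delim, lineterminator="\n")
        w.writerow(["#taxon", *matrix.char_names])
        for taxon, row in zip(matrix.taxa, matrix.cells):
            w.writerow([taxon, *(_symbol(s) for s in row)])
        return out.getvalue()
    if kind == "tnt":
        lines = [f"xread 'parsclad export' {matrix.n_characters} {matrix.n_taxa}"]
        for taxon, row in zip(matrix.taxa, matrix.cells):
            lines.append(f"{taxon} {''.join(_symbol(s) for s in row)}")
        lines.append(";")
        return "\n".join(lines) + "\n"
    return _write_nexus(matrix)


def _symbol(state: int) -> str:
    return "?" if state == MISSING else str(int(state))


def _nexus_label(label: str) -> str:
    if any(c.isspace() or c in "()[]{}/\\,;:=*'\"`+<>" for c in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _write_nexus(matrix: CharacterMatrix) -> str:
    width = max(len(_nexus_label(t)) for t in matrix.taxa) + 2
    lines = [
        "#NEXUS",
        "",
        "BEGIN CHARACTERS;",
        f"    DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_characters};",
        '    FORMAT DATATYPE=STANDARD SYMBOLS="0123456789" MISSING=?;',
        "    MATRIX",
    ]
    for taxon, row in zip(matrix.taxa, matrix.cells):
        states = "".join(_symbol(s) for s in row)
        lines.append(f"        {_nexus_label(taxon):<{width}}{states}")
    lines += ["    ;", "END;", ""]
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# bundled dataset and summary


def load_bundled_matrix() -> CharacterMatrix:
    """The bundled saltans-group terminalia matrix (11 taxa x 19 characters).

    Taxon order and 1-based character numbering follow the published table;
    the outgroup is preset to ``willistoni``.
    """
    text = (resources.files("parsclad.data") / "saltans_table2.csv").read_text()
    m = parse_matrix(text, "csv")
    m.outgroup = "willistoni"
    return m


def summarize(matrix: CharacterMatrix) -> MatrixSummary:
    """Classify every character as constant, autapomorphic or informative.

    A character is parsimony-informative iff at least two distinct states
    each occur in two or more taxa; a variable but uninformative character
    is autapomorphic.  Missing cells are ignored in the census.
    """
    state_counts: list[Counter] = []
    constant: list[int] = []
    autapo: list[int] = []
    informative: list[int] = []
    for cid in matrix.char_ids:
        col = matrix.column(cid)
        counts = Counter(int(s) for s in col if s != MISSING)
        state_counts.append(counts)
        if len(counts) <= 1:
            constant.append(cid)
        elif sum(1 for n in counts.values() if n >= 2) >= 2:
            informative.append(cid)
        else:
            autapo.append(cid)
    n_ingroup = matrix.n_taxa - (1 if matrix.outgroup else 0)
    return MatrixSummary(
        n_taxa=matrix.n_taxa,
        n_characters=matrix.n_characters,
        n_ingroup=n_ingroup,
        state_counts=state_counts,
        constant=constant,
        autapomorphic=autapo,
        informative=informative,
    )
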