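"""Exception hierarchy shared across the package."""


class ParscladError(Exception):
    """Base class for all package-specific errors."""


class MatrixError(ParscladError, ValueError):
    """Invalid character-matrix content or a matrix parse failure."""


class TreeError(ParscladError, ValueError):
    """Invalid tree structure or a newick parse failure."""


class CapExceededError(ParscladError, RuntimeError):
    """A resource cap was hit (combinatorial enumeration, MPR explosion)."""
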