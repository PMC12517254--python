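"""Exception hierarchy for the comparative-dynamics pipeline."""


class DynatileError(Exception):
    """Base class for all package errors."""


class FormatError(DynatileError):
    """A structure file could not be parsed."""


class EmptyModelError(DynatileError):
    """No polymer residues with an alpha-carbon survived parsing/filtering."""


class DegenerateGeometryError(DynatileError):
    """Two network nodes coincide within the spring cutoff."""


class ModeCountError(DynatileError):
    """Fewer non-trivial normal modes available than requested."""


class DegenerateMobilityError(DynatileError):
    """A residue has zero mean-square fluctuation in the retained modes."""


class UndefinedSimilarityError(DynatileError):
    """A similarity is undefined for the given input (e.g. zero vector)."""


class BoundError(DynatileError):
    """A tiling bound violates the method's limits (minimum tile length 6)."""


class UndefinedCorrelationError(DynatileError):
    """Pearson correlation undefined because a metric column is constant."""


class InsufficientDataError(DynatileError):
    """Not enough points for the requested regression/convergence analysis."""


class ConfigError(DynatileError):
    """Invalid or incomplete pipeline configuration."""
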