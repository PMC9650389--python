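"""Exception hierarchy.

Exit-code mapping used by the CLI: :class:`ConfigError` -> 2,
:class:`DataError` (and subclasses) -> 3.
"""


class MepclustError(Exception):
    """Base class for all package errors."""


class ConfigError(MepclustError):
    """Invalid or contradictory run configuration."""


class DataError(MepclustError):
    """A problem with the input data encountered at some pipeline stage."""


class ParseError(DataError):
    """A coordinate record could not be parsed (message names the line)."""


class DegenerateFitError(DataError):
    """Too few or collinear atom pairs for a rigid superposition."""


class EmptyMaskError(DataError):
    """A region mask (skin, cylinder, or pairwise comparison) is empty."""


class UndefinedSimilarityError(DataError):
    """Both potentials vanish on the comparison mask; SI is undefined."""


class ZeroVarianceError(DataError):
    """A similarity-profile column has zero variance; correlation undefined."""
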