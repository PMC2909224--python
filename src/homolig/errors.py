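"""Exception hierarchy for homolig.

All library-raised errors derive from :class:`HomoligError` so callers can
catch one base class at pipeline boundaries.
"""


class HomoligError(Exception):
    """Base class for all homolig errors."""


class FormatError(HomoligError):
    """A file does not parse under the named standard."""


class EmptyStructureError(HomoligError):
    """A structure file contains no polymer chain."""


class LigandLookupError(HomoligError):
    """A ligand instance does not belong to the given complex."""


class DataError(HomoligError):
    """Required derived data (e.g. molecular weight) is missing."""


class MalformedAlignmentError(HomoligError):
    """Alignment pairs cross or repeat residues."""


class CoordinateError(HomoligError):
    """A residue index falls outside the chain it refers to."""


class UndefinedIdentityError(HomoligError):
    """Percent identity requested for an alignment with no aligned position."""


class CompositionError(HomoligError):
    """Two alignments cannot be composed (different query)."""


class FrameError(HomoligError):
    """Sites or scores requested in an alignment frame that does not hold them."""


class SubstitutionLookupError(HomoligError):
    """A residue code has no row in the substitution matrix."""


class DegenerateSiteError(HomoligError):
    """A site whose self bit score is non-positive cannot be normalized."""


class GenerationError(HomoligError):
    """Synthetic family generation hit an infeasible geometry."""
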