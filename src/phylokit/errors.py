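"""Exception hierarchy shared across the toolchain.

Every error raised by phylokit derives from :class:`PhylokitError`, so CLI
wrappers can catch one type and turn it into a one-line diagnostic with a
non-zero exit status.
"""


class PhylokitError(Exception):
    """Base class for all phylokit errors."""


class AlignmentShapeError(PhylokitError):
    """Sequences in one alignment have unequal lengths."""


class IdentifierCollisionError(PhylokitError):
    """Two records resolve to the same taxon identifier."""


class EmptyInputError(PhylokitError):
    """A stream that must contain records contains none."""


class AlphabetError(PhylokitError):
    """A sequence contains a character outside the declared alphabet."""


class ParseError(PhylokitError):
    """Malformed text input (PHYLIP, Newick, distance matrix ...)."""


class ValidationError(PhylokitError):
    """An XML document does not conform to the embedded schema."""


class FormatError(PhylokitError):
    """A binary stream has a bad magic number, version, or length."""


class UnsupportedCombinationError(PhylokitError):
    """Mutually exclusive options requested together (e.g. streaming + ambiguity)."""


class SaturationError(PhylokitError):
    """A distance correction was evaluated outside its domain."""


class DegenerateCompositionError(PhylokitError):
    """A base-frequency class required by an estimator is empty."""


class DegeneratePosteriorError(PhylokitError):
    """Posterior mass underflowed to zero on the whole prior grid."""
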