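"""Exception hierarchy.

Every error raised deliberately by this package derives from
:class:`LogoplotError`, so callers can catch one type.  The CLI maps
subfamilies onto exit codes (parse errors → 2, transform errors → 3,
I/O errors → 4).
"""


class LogoplotError(Exception):
    """Base class for all logoplot errors."""


class MatrixValidationError(LogoplotError):
    """A position-by-character matrix violates the invariants of its type."""


class NormalizationError(MatrixValidationError):
    """A probability row is too far from summing to 1 to renormalize."""


class DegeneratePositionError(LogoplotError):
    """A counts row sums to zero and no pseudocount was supplied."""


class ZeroProbabilityError(LogoplotError):
    """A zero probability was passed to a log-odds transform.

    Log-odds of a zero probability is -inf, which cannot be drawn; the
    caller should apply a pseudocount when building the probability
    matrix.
    """


class TransformRangeError(LogoplotError):
    """A weight value is too large in magnitude to exponentiate."""


class SemanticTypeError(LogoplotError):
    """An operation was applied to a matrix type it would corrupt."""


class DispatchError(LogoplotError):
    """Requested matrix conversion pair is not supported."""


class RaggedAlignmentError(LogoplotError):
    """Sequences in an alignment do not all share one length."""


class FastaFormatError(LogoplotError):
    """Input could not be parsed as FASTA."""


class AlphabetError(LogoplotError):
    """A sequence character falls outside the declared alphabet."""


class LayoutError(LogoplotError):
    """Non-finite value encountered while stacking glyphs."""


class GlyphError(LogoplotError):
    """A character has no usable outline (degenerate bounding box)."""


class RenderError(LogoplotError):
    """The matrix cannot be rendered (e.g. it is empty)."""


class GlyphLookupError(LogoplotError):
    """No glyph exists at the requested (position, character)."""


class ColorSchemeError(LogoplotError):
    """Unknown color-scheme name."""


class HighlightRangeError(LogoplotError):
    """Highlight interval falls outside the matrix positions."""
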