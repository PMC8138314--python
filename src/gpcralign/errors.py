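"""Exception hierarchy for gpcralign.

All package-specific failures derive from :class:`GpcrAlignError` so callers
(and the CLI) can separate validation problems from genuine runtime faults.
"""


class GpcrAlignError(Exception):
    """Base class for all gpcralign errors."""


class ParseError(GpcrAlignError):
    """A structure, annotation, matrix or manifest file could not be parsed."""


class ValidationError(GpcrAlignError):
    """Inputs are well-formed but violate a contract (counts, signs, ranges)."""


class AmbiguousLigandError(ValidationError):
    """Automatic ligand detection found zero or several candidate components."""

    def __init__(self, message: str, candidates: list[str] | None = None):
        super().__init__(message)
        self.candidates = candidates or []


class DegenerateReferenceError(GpcrAlignError):
    """Reference self-alignment score R is zero; N = T/R is undefined."""


class FixtureGeometryError(GpcrAlignError):
    """A synthetic fixture plan is geometrically infeasible."""
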