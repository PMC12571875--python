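"""Exception hierarchy.

All glomscape errors derive from :class:`GlomscapeError` so callers can catch
the package's failures with a single ``except`` clause; subclasses mirror the
contract violations of the individual stages.
"""


class GlomscapeError(Exception):
    """Base class for all glomscape errors."""


class SchemaError(GlomscapeError):
    """An input table is missing a required column or has a malformed header."""


class AlignmentError(GlomscapeError):
    """Row counts of paired inputs (cells table vs. count matrix) disagree."""


class ValidationError(GlomscapeError):
    """Input values violate an invariant (negative counts, non-finite coords)."""


class ParameterError(GlomscapeError):
    """A parameter is outside its documented domain."""


class CompatibilityError(GlomscapeError):
    """Model and data are incompatible (e.g. insufficient gene overlap)."""


class GeometryError(GlomscapeError):
    """Synthetic tissue geometry cannot be realised (disc placement failed)."""


class DegenerateInputError(GlomscapeError):
    """The input is degenerate for the requested computation (e.g. constant
    vector passed to a natural-breaks classifier)."""


class TrainingError(GlomscapeError):
    """Reference data are unsuitable for classifier training."""


class EmptyGeneSetError(GlomscapeError):
    """No gene of a requested gene set is present in the panel."""

    def __init__(self, set_name: str, missing: list):
        self.set_name = set_name
        self.missing = list(missing)
        super().__init__(
            f"no gene of set {set_name!r} is present in the panel; "
            f"missing: {', '.join(self.missing[:10])}"
            + ("..." if len(self.missing) > 10 else "")
        )
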