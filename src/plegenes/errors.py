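"""Package exceptions."""


class PleError(Exception):
    """Base class for plegenes errors."""


class InvalidSpecError(PleError, ValueError):
    """A synthetic-data or alignment parameter specification is invalid."""


class TranslationError(PleError, ValueError):
    """A coding sequence cannot be translated (internal stop, bad length...)."""


class AmbiguousOrderError(PleError):
    """The clone-overlap graph is not a set of simple paths."""

    def __init__(self, clones):
        self.clones = sorted(clones)
        super().__init__(
            "clone overlap graph is branching or cyclic; cannot order clones: "
            + ", ".join(self.clones)
        )


class GFF3ParseError(PleError, ValueError):
    """Malformed GFF3 input; carries the offending line number."""

    def __init__(self, message, line_number=None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
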