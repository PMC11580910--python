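"""Exception hierarchy.

Three error classes matter to callers (and map to distinct CLI exit codes):
I/O problems (missing files, unwritable paths — plain ``OSError`` family),
configuration problems (impossible option combinations, unsupported formats),
and data problems (malformed or inconsistent input).
"""


class IsovizError(Exception):
    """Base class for all isoviz-specific errors."""


class ConfigurationError(IsovizError):
    """An option combination or value that can never be valid."""


class UnsupportedFormatError(ConfigurationError):
    """A file extension or export format the package does not handle."""


class ValidationError(IsovizError):
    """Input data that violates a structural contract."""


class FormatError(ValidationError):
    """A file whose contents do not follow its declared format."""


class EmptyAnnotationError(ValidationError):
    """An annotation table left empty after filtering."""


class GeneNotFoundError(ValidationError):
    """Requested gene absent from the annotation.

    Carries suggestions of near-matching gene identifiers.
    """

    def __init__(self, gene: str, suggestions: list[str] | None = None):
        self.gene = gene
        self.suggestions = suggestions or []
        msg = f"gene {gene!r} not found in annotation"
        if self.suggestions:
            msg += "; nearest matches: " + ", ".join(self.suggestions)
        super().__init__(msg)


class MergeError(ValidationError):
    """Samples in the expression matrix that have no metadata row."""


class SynchronizationError(ValidationError):
    """Expression transcripts absent from the annotation being plotted."""
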