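"""Exception types shared across the package."""


class UniredError(Exception):
    """Base class for all package errors."""


class FormatError(UniredError, ValueError):
    """An input table or list does not match the documented dialect."""


class BuildError(UniredError, ValueError):
    """Knowledge-base construction failed an integrity check."""


class SchemaError(UniredError, ValueError):
    """A serialized knowledge base violates the JSON schema."""


class AnalysisError(UniredError, ValueError):
    """User-facing analysis error (e.g. no analyzable query proteins)."""
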