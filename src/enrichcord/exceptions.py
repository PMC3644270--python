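"""Exception hierarchy shared across the pipeline."""


class EnrichcordError(Exception):
    """Base class for all package-specific errors."""


class FormatError(EnrichcordError, ValueError):
    """A file violates the expected on-disk format or an input object an invariant."""


class ParameterError(EnrichcordError, ValueError):
    """An argument is outside its documented domain."""


class DataError(EnrichcordError, ValueError):
    """Input values are structurally valid but statistically unusable."""


class AnalysisError(EnrichcordError, RuntimeError):
    """A computation cannot proceed on the given inputs (e.g. empty intersection)."""
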