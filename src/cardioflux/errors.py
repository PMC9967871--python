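"""Structured exceptions raised across the package."""


class CardiofluxError(Exception):
    """Base class for all cardioflux errors."""


class FormatError(CardiofluxError):
    """A file could not be parsed into a valid domain object."""


class ValidationError(CardiofluxError):
    """A domain-object invariant was violated."""


class AnalysisError(CardiofluxError):
    """An analysis step could not produce a result."""


class FitError(AnalysisError):
    """A curve fit failed to converge or was ill-posed."""
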