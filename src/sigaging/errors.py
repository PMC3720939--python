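"""Exception hierarchy for the sigaging package."""


class SigagingError(Exception):
    """Base class for all package-specific errors."""


class SvcFormatError(SigagingError):
    """A file does not conform to the SVC plain-text layout."""


class SignatureValidationError(SigagingError):
    """A dynamic signature violates a structural invariant."""


class GenerationError(SigagingError):
    """The synthetic generator was asked for a physically impossible sample."""


class ProtocolError(SigagingError):
    """A score protocol cannot be run on the given dataset."""


class PreprocessingError(SigagingError):
    """A signature is too degenerate to preprocess (e.g. all points equal)."""
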