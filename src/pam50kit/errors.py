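"""Exception hierarchy shared by all pam50kit modules."""


class Pam50KitError(Exception):
    """Base class for all package-specific errors."""


class FormatError(Pam50KitError):
    """A file does not conform to the expected dialect (bad header, bad section)."""


class ValidationError(Pam50KitError):
    """Parsed data violates an invariant (negative count, unknown class, ...)."""


class AmbiguousMergeError(ValidationError):
    """Gene-identifier harmonization would collapse two distinct input genes."""


class NormalizationError(Pam50KitError):
    """A normalization precondition failed (too few negatives, zero quartile, ...)."""


class ClassificationError(Pam50KitError):
    """The classifier cannot produce a call (missing gene, constant profile, ...)."""


class ConcordanceError(Pam50KitError):
    """An agreement statistic is undefined for the given input."""
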