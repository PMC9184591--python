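"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when parameters or inputs fail validation."""


class DesignError(ValueError):
    """Raised when a regression design matrix is rank deficient.

    The message names the offending column so scan logs are actionable.
    """


class AlignmentError(ValueError):
    """Raised when genotype and phenotype tables disagree on subject ids."""
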