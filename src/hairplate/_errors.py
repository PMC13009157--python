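"""Exception types shared across the package."""


class FormatError(ValueError):
    """A table on disk does not conform to the expected schema."""


class SpecError(ValueError):
    """A synthetic-data specification is internally inconsistent or infeasible."""


class DegenerateBaselineError(ValueError):
    """The ratio baseline has zero variance, so z-scoring is undefined."""


class UndefinedFractionError(ValueError):
    """A normalization denominator (e.g. total module input) is zero."""
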