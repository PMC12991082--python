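"""Exception types shared across the pipeline."""


class VasotraceError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(VasotraceError, ValueError):
    """A synthetic-data spec violates its invariants."""


class InvalidArgumentError(VasotraceError, ValueError):
    """An operation received an argument outside its contract."""


class TooShortError(VasotraceError, ValueError):
    """A line scan is too short to partition into blocks."""


class UndefinedAngleError(VasotraceError, ValueError):
    """A kymograph block carries no structure; the Radon peak is undefined."""


class OpenProfileError(VasotraceError, ValueError):
    """An intensity profile never crosses its half-maximum on one side."""


class SingularDesignError(VasotraceError, ValueError):
    """The regression design matrix is rank deficient."""


class DegenerateCurveError(VasotraceError, ValueError):
    """A trajectory has zero variance and cannot be z-scored."""


class SchemaError(VasotraceError, ValueError):
    """A table is missing required columns or is empty."""


class PathIntegrityError(VasotraceError, ValueError):
    """A skeleton path strays outside the mask that produced it."""
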