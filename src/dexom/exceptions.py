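"""Exception hierarchy shared across the package."""


class DexomError(Exception):
    """Base class for all package-specific errors."""


class FormatError(DexomError, ValueError):
    """A model or solution file could not be parsed."""


class ValidationError(DexomError, ValueError):
    """A data structure violates one of its invariants."""


class DimensionError(DexomError, ValueError):
    """Vector/matrix sizes are inconsistent with the model."""


class InfeasibleProblemError(DexomError, RuntimeError):
    """An LP/MILP that was expected to be feasible is not."""


class UndefinedMetricError(DexomError, ValueError):
    """A diversity metric was requested on a set that is too small."""


class UndefinedEssentialityError(DexomError, RuntimeError):
    """Gene essentiality is undefined (zero wild-type objective)."""
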