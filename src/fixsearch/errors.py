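"""Exception types shared across the package."""


class FixsearchError(Exception):
    """Base class for package errors."""


class ParameterError(FixsearchError, ValueError):
    """A configuration or argument value violates its contract."""


class GeometryError(FixsearchError, ValueError):
    """A spatial precondition fails (object outside image, window too large, ...)."""


class DegeneratePatchError(FixsearchError, ValueError):
    """A patch admits no valid pixel pair for any co-occurrence offset."""


class ContractError(FixsearchError, ValueError):
    """An input object violates a documented invariant (e.g. unnormalized GLCM)."""


class InsufficientDataError(FixsearchError, ValueError):
    """Too few observations for the requested statistic."""
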