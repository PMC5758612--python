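"""Exception hierarchy shared across the package."""


class LatmaskError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(LatmaskError, ValueError):
    """A numeric parameter is outside its valid range."""


class GeometryError(LatmaskError, ValueError):
    """A stimulus element does not fit the display raster."""


class ConfigurationError(LatmaskError, ValueError):
    """An observer or experiment is queried for an unknown condition."""


class PairingError(LatmaskError, ValueError):
    """A row that should have a matching partner (collinear/orthogonal,
    pre/post) is missing it."""


class DesignError(LatmaskError, ValueError):
    """A factorial design is incomplete, unbalanced, or asks for an
    analysis the implemented tests do not support."""


class IntegrityError(LatmaskError, ValueError):
    """A packaged fixture does not match its recorded checksum."""


class StaircaseWarning(UserWarning):
    """A staircase terminated without enough reversals for a valid
    threshold estimate."""
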