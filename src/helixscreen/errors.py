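"""Exception hierarchy shared across the package."""


class HelixScreenError(Exception):
    """Base class for all package-specific errors."""


class StructureParseError(HelixScreenError):
    """A coordinate file could not be parsed or is empty."""


class ConfidenceError(HelixScreenError):
    """Confidence data is malformed, out of range, or absent when required."""


class AbsentPAEError(ConfidenceError):
    """An operation needed a PAE matrix but the confidence source had none."""


class GeometryError(HelixScreenError):
    """A geometric precondition failed (missing atoms, degenerate input)."""


class RegisterError(HelixScreenError):
    """No helical register could be assigned (e.g. non-canonical binder)."""


class InfeasibleFixtureError(HelixScreenError):
    """A synthetic fixture specification cannot be realised geometrically."""
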