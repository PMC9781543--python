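"""Exception types raised across the package."""


class HistostereoError(Exception):
    """Base class for all package errors."""


class GeometryError(HistostereoError):
    """Invalid region geometry (non-positive semi-axes, empty mask, ...)."""


class SimulationError(HistostereoError):
    """Invalid simulation parameters (negative density, bad label probabilities)."""


class UndefinedCEError(HistostereoError):
    """Coefficient of error requested for an all-zero count sequence."""


class ProbeError(HistostereoError):
    """Invalid probe input (empty stack, zero sites, bad design)."""


class MissingColumnError(HistostereoError):
    """A required column is absent from a marker/fiber table."""


class CoordinateParseError(HistostereoError):
    """A coordinate column contains non-numeric values."""


class UnknownLabelError(HistostereoError):
    """A categorical column contains a value outside the documented vocabulary."""


class ConfigError(HistostereoError):
    """Study configuration is invalid; ``key`` names the offending entry."""

    def __init__(self, key: str, message: str):
        self.key = key
        super().__init__(f"config key {key!r}: {message}")
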