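"""Exception hierarchy.

Everything raised deliberately by thermopulse derives from
:class:`ThermoPulseError`, so callers can catch one type at the
pipeline boundary (the CLI does exactly that).
"""


class ThermoPulseError(Exception):
    """Base class for all thermopulse errors."""


class InvalidMaterialError(ThermoPulseError):
    """A material property is non-physical (non-positive k, rho or cp)."""


class ConfigurationError(ThermoPulseError):
    """A stack, grid, protocol or scenario configuration is inconsistent."""


class SchemaError(ThermoPulseError):
    """A CSV/YAML file does not conform to the declared schema."""


class WindowError(ThermoPulseError):
    """A regression or endpoint window selects too few samples."""


class FitError(ThermoPulseError):
    """A regression/fit cannot be performed on the given data."""
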