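"""Exception and warning types shared across the package."""


class AngiocamError(Exception):
    """Base class for all package-specific errors."""


class GraphValidationError(AngiocamError, ValueError):
    """A vessel graph violates a structural invariant."""


class InvalidROIError(AngiocamError, ValueError):
    """The ring region of interest is geometrically invalid (e.g. zero area)."""


class InvalidBaselineError(AngiocamError, ValueError):
    """A day-0 / baseline measurement is nonpositive, so a fold change is undefined."""


class DegenerateControlError(AngiocamError, ValueError):
    """The control group's baseline-corrected change is ~0; the AAI denominator vanishes."""


class EmptyGroupError(AngiocamError, ValueError):
    """No eligible embryos/records remain for the requested group and day."""


class NoValidParametersError(AngiocamError, ValueError):
    """Every parameter was excluded; the final AAI is undefined."""


class SchemaError(AngiocamError, ValueError):
    """An input file does not match its documented schema."""


class DisconnectedNetworkWarning(UserWarning):
    """Segments unreachable from any root were assigned the finest branch degree."""
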