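"""Exception types for the force-volume analysis pipeline."""


class FDMechError(Exception):
    """Base class for all package errors."""


class SchemaError(FDMechError):
    """A container file violates the documented schema; names the field."""


class ParameterError(FDMechError):
    """An operation received a physically invalid parameter."""


class DomainError(FDMechError):
    """An input is outside the mathematical domain of a model."""


class InsufficientDataError(FDMechError):
    """Too few samples to carry out a fit or estimate."""


class ChannelError(FDMechError):
    """A derived channel was requested before being computed."""


class ConfigError(FDMechError):
    """A run configuration violates its schema; names the key."""
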