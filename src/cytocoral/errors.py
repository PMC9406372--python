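"""Typed exception hierarchy shared across the toolkit."""


class CytocoralError(Exception):
    """Base class for all toolkit errors."""


class FormatError(CytocoralError):
    """A manifest or config file does not parse to the expected schema."""


class DomainError(CytocoralError):
    """An argument is outside its documented domain."""


class CapacityError(CytocoralError):
    """An augmentation request exceeds the distinct-transform budget."""


class SpecError(CytocoralError):
    """An architecture specification is internally inconsistent."""


class ContractError(CytocoralError):
    """Inputs violate an operation's calling contract (shapes, lengths)."""


class ConfigError(CytocoralError):
    """An experiment configuration fails schema validation."""
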