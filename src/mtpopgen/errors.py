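"""Exception hierarchy shared across the package."""


class MtPopGenError(Exception):
    """Base class for all package errors."""


class FormatError(MtPopGenError):
    """A file does not conform to the expected format."""


class InputError(MtPopGenError):
    """Input values violate a precondition."""


class ConfigurationError(MtPopGenError):
    """A configuration object is internally inconsistent."""


class ModelError(MtPopGenError):
    """A demographic model cannot be simulated as specified."""


class ClassificationError(MtPopGenError):
    """A variant cannot be assigned to a functional class."""
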