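"""Exception hierarchy for uvidose."""


class UviDoseError(Exception):
    """Base class for all package errors."""


class InvalidInputError(UviDoseError, ValueError):
    """An argument violates a documented precondition."""


class NoDataError(UviDoseError):
    """A computation has no usable data to operate on."""


class ParseError(UviDoseError, ValueError):
    """A CSV table or timestamp failed validation; message names the row."""


class ConfigError(UviDoseError, ValueError):
    """A configuration file is malformed or incomplete."""
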