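"""Exception hierarchy shared by all stages."""


class EnzdesignError(Exception):
    """Base class for all package errors."""


class InputError(EnzdesignError):
    """Malformed or inconsistent input data (wrong lengths, missing records)."""


class FormatError(InputError):
    """A file failed to parse in its declared format."""


class ParameterError(EnzdesignError):
    """A parameter is outside its documented range."""


class ValidationError(EnzdesignError):
    """A domain object violates one of its invariants."""
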