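"""Exception hierarchy shared across the pipeline."""


class AccelAgeError(Exception):
    """Base class for all package errors."""


class SchemaError(AccelAgeError):
    """An input table is missing a required column or has the wrong layout."""


class ValidationError(AccelAgeError):
    """Input data violates a contract (duplicate ids, missing link, ...)."""


class ParameterError(AccelAgeError):
    """A user-supplied parameter is out of its allowed range."""


class ContractError(AccelAgeError):
    """An operation was called on data that skipped a required earlier step."""


class DegenerateInputError(AccelAgeError):
    """The computation is undefined on this input (zero variance, bad median)."""
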