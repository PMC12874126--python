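"""Exception hierarchy for duckreq."""


class DuckReqError(Exception):
    """Base class for all duckreq errors."""


class InvalidInputError(DuckReqError, ValueError):
    """A physically or numerically invalid input (negative weight, non-finite
    temperature, zero methionine, ...)."""


class ConfigurationError(DuckReqError):
    """A table, registry or fit configuration is incomplete or degenerate
    (missing season zone, zero-variance calibration target, ...)."""


class SchemaError(DuckReqError, ValueError):
    """A flock CSV does not conform to the documented column schema."""


class BreedNotFoundError(DuckReqError, KeyError):
    """Requested breed label is absent from the registry."""
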