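"""Exception hierarchy shared across the pipeline."""


class LibioError(Exception):
    """Base class for all package errors."""


class FormatError(LibioError):
    """A file does not conform to its declared on-disk format."""


class IntegrityError(LibioError):
    """Data violate an internal invariant (duplicates, mismatched ids, ...)."""


class SchemaError(LibioError):
    """A required column or field is missing."""


class ConfigError(LibioError):
    """A configuration value is invalid or refers to missing entities."""


class InputError(LibioError):
    """An operation received input outside its domain."""


class PipelineError(LibioError):
    """A pipeline stage produced an unusable result (e.g. empty signature)."""


class DependencyError(LibioError):
    """A pipeline stage was invoked before the stages it depends on."""


class CalibrationError(LibioError):
    """Threshold calibration found no admissible threshold."""
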