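"""Exception hierarchy shared across the pipeline."""


class VitYieldError(Exception):
    """Base class for package errors."""


class InvalidArgumentError(VitYieldError, ValueError):
    """A caller-supplied value violates an operation's preconditions."""


class ConfigurationError(VitYieldError, ValueError):
    """Inconsistent model/run configuration."""


class DataError(VitYieldError):
    """A data artifact (manifest row, image file) is missing or corrupt."""


class SchemaError(DataError):
    """A tabular input lacks required columns."""


class UndefinedMetricError(VitYieldError, ValueError):
    """Metric undefined for the given inputs (e.g. constant ground truth)."""
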