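"""Exception hierarchy for incompfs.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError (and
subclasses) -> 3.
"""


class IncompfsError(Exception):
    """Base class for all incompfs errors."""


class ConfigError(IncompfsError):
    """Invalid configuration (bad parameter value, missing label field...)."""


class DataError(IncompfsError):
    """Invalid or unusable input data."""


class FormatError(DataError):
    """A cell could not be parsed and is not a declared missing token."""


class DegenerateFeatureError(DataError):
    """A feature has no observed values (or otherwise cannot be processed)."""

    def __init__(self, features, message=None):
        self.features = list(features)
        super().__init__(message or f"degenerate feature(s): {self.features}")


class UnsupervisedInputError(DataError):
    """Fewer than two observed classes remain after dropping missing labels."""
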