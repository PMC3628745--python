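"""Exception hierarchy shared by the library and the CLI.

Each branch maps to a CLI exit code: configuration problems exit 2,
data/format problems exit 3, evaluation failures exit 4.
"""


class GwsigError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(GwsigError):
    """Invalid configuration (unknown keys, impossible parameter combinations)."""

    exit_code = 2


class DataError(GwsigError):
    """Malformed or inconsistent input data."""

    exit_code = 3


class FormatError(DataError):
    """A file does not parse as the expected tabular dialect."""


class LabelError(DataError):
    """Sample labels missing or not forming exactly two classes."""


class EvaluationError(GwsigError):
    """Classifier evaluation could not be carried out."""

    exit_code = 4
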