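"""Exception hierarchy shared across the pipeline.

Config problems (bad parameters, missing mappings) and data problems
(malformed tables, impossible values) are kept distinct so the CLI can map
them to different exit codes.
"""


class MnapportError(Exception):
    """Base class for all package errors."""


class ConfigError(MnapportError):
    """Invalid configuration: bad parameter values, unmapped food items,
    missing requirement entries."""


class DataError(MnapportError):
    """Invalid data content: negative concentrations, censored values
    without a detection limit, non-finite pH."""


class SchemaError(DataError):
    """A table does not match its column contract."""


class ParseError(DataError):
    """A cell could not be parsed; message names the row and column."""
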