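"""Exception hierarchy shared across the pipeline.

Configuration errors (bad parameters, invalid barcode sets, missing
references) map to CLI exit code 2; data errors (malformed or out-of-range
records) map to exit code 3.
"""


class MinquantError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(MinquantError):
    exit_code = 2


class DataError(MinquantError):
    exit_code = 3
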