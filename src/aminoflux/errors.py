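"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: validation / input problems exit with 2,
numerical failures with 3.
"""


class AminofluxError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputError(AminofluxError, ValueError):
    """Invalid data handed to an operation (wrong shape, sign, count...)."""

    exit_code = 2


class ConfigError(AminofluxError, ValueError):
    """Invalid configuration; the message names the offending field."""

    exit_code = 2


class ParseError(InputError):
    """File-level validation failure; message lists offending rows/columns."""

    exit_code = 2


class ModelError(AminofluxError, RuntimeError):
    """Numerical / statistical model failure (singular design, bad fit)."""

    exit_code = 3
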