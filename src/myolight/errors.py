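"""Exception hierarchy shared by all pipeline stages.

Each class carries the process exit code the command-line layer maps it to,
so stage failures surface with distinct, scriptable codes.
"""


class MyolightError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(MyolightError):
    """Invalid run configuration, protocol, or model specification."""

    exit_code = 2


class FormatError(MyolightError):
    """Malformed on-disk session data or an inconsistent sidecar."""

    exit_code = 3


class ContractError(MyolightError):
    """A stage received inputs violating its preconditions (shape, labels, counts)."""

    exit_code = 4


class DomainError(ContractError):
    """A metric was evaluated outside its mathematical domain (e.g. zero denominator)."""
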