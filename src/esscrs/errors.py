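"""Exception hierarchy.

Input errors (bad data) and configuration errors (bad algorithm / option
wiring) are distinct so the CLI can map them to distinct exit codes.
"""


class EssCrsError(Exception):
    """Base class for all package errors."""


class InputError(EssCrsError):
    """Malformed or inconsistent input data (CSV rows, labels, counts)."""


class InvalidCodeError(InputError):
    """A raw administrative code that cannot be normalized."""


class ConfigurationError(EssCrsError):
    """An algorithm, clause, or option that is wired up incorrectly."""


class NoSolutionError(EssCrsError):
    """The joint-count solver found no (or no unique) integer solution."""

    def __init__(self, message: str, constraint: str | None = None):
        super().__init__(message)
        self.constraint = constraint
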