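"""Exception hierarchy shared across the package.

Two failure classes are distinguished so the command-line layer can map them
to distinct exit codes: malformed inputs/configuration (exit 2) versus data
that parses fine but cannot be analyzed (exit 3).
"""


class OscsyncError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(OscsyncError, ValueError):
    """Invalid configuration, parameters, or file contents."""

    exit_code = 2


class AnalysisError(OscsyncError, RuntimeError):
    """Structurally valid input that cannot be analyzed (e.g. dead trace)."""

    exit_code = 3
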