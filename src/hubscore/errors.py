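"""Exception hierarchy used across the package.

All data-facing errors derive from :class:`HubscoreError` so the CLI can map
them onto exit codes (usage=1, data/format=2, internal=3).
"""


class HubscoreError(Exception):
    """Base class for all package errors."""


class FormatError(HubscoreError):
    """A file does not conform to the expected tabular dialect."""


class ParseError(HubscoreError):
    """A row or cell could not be interpreted.

    Parameters
    ----------
    message:
        Human-readable description.
    line:
        1-based line number in the offending file, if known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConsistencyError(HubscoreError):
    """In-memory inputs contradict each other (e.g. mixed cancer ids)."""


class ConfigError(HubscoreError):
    """A configuration value is invalid or infeasible."""
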