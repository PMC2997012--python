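"""Exception hierarchy.

Config problems map to CLI exit code 2, data problems to exit code 3.
"""


class MotifMethylomeError(Exception):
    """Base class for all package errors."""


class ConfigError(MotifMethylomeError):
    """Invalid configuration; names the offending field where possible."""

    def __init__(self, message: str, field: str | None = None):
        self.field = field
        if field is not None:
            message = f"{field}: {message}"
        super().__init__(message)


class DataError(MotifMethylomeError):
    """Base for problems with input data."""


class BedParseError(DataError):
    """Malformed BED line; carries the 1-based line number."""

    def __init__(self, message: str, path=None, lineno: int | None = None):
        self.path = path
        self.lineno = lineno
        prefix = ""
        if path is not None:
            prefix += f"{path}:"
        if lineno is not None:
            prefix += f"{lineno}:"
        super().__init__(f"{prefix} {message}" if prefix else message)


class BedGraphFormatError(DataError):
    """Malformed or inconsistent bedGraph (window size, value range)."""

    def __init__(self, message: str, path=None, lineno: int | None = None):
        self.path = path
        self.lineno = lineno
        prefix = ""
        if path is not None:
            prefix += f"{path}:"
        if lineno is not None:
            prefix += f"{lineno}:"
        super().__init__(f"{prefix} {message}" if prefix else message)


class PlacementError(DataError):
    """Requested feature counts exceed the available placement space."""


class BoundsError(DataError):
    """A segment or interval lies outside its sequence/chromosome."""


class EmptyProfileError(DataError):
    """No usable anchors remain after edge filtering."""
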