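"""Exception hierarchy shared across the pipeline."""


class AlevbmError(Exception):
    """Base class for all package errors."""


class ValidationError(AlevbmError):
    """Invalid data or parameter values supplied by the caller."""


class ConfigurationError(AlevbmError):
    """Inconsistent or degenerate configuration (bad grid, empty mask, ...)."""


class FormatError(AlevbmError):
    """Malformed input file (unreadable NIfTI, wrong dimensionality, ...)."""


class TableParseError(ValidationError):
    """One or more rows of a tabular input failed to parse.

    Collects every per-row problem so a user sees all of them at once.
    """

    def __init__(self, errors):
        self.errors = list(errors)
        msg = "; ".join(self.errors)
        super().__init__(f"{len(self.errors)} row error(s): {msg}")
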