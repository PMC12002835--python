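"""Exception hierarchy shared across the package.

Degenerate *data* (a constant gene, a protein with too few valid values)
is flagged in results rather than raised, so that genome-scale loops can
continue; exceptions are reserved for invalid *inputs* (malformed files,
impossible parameters, broken designs).
"""


class VascageError(Exception):
    """Base class for all package errors."""


class ValidationError(VascageError):
    """An input value or structure violates a documented precondition."""


class PValueError(ValidationError):
    """A p-value is outside [0, 1] or not finite."""


class CollinearityError(ValidationError):
    """A regression design matrix is rank deficient."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            f"design matrix is rank deficient; collinear columns: {self.columns}"
        )


class PanelMappingError(ValidationError):
    """Too few panel symbols map into the gene universe."""

    def __init__(self, panel_name, unmapped):
        self.panel_name = panel_name
        self.unmapped = sorted(unmapped)
        super().__init__(
            f"panel {panel_name!r}: fewer than 50% of symbols map into the "
            f"gene universe; unmapped: {self.unmapped}"
        )


class ParseError(VascageError):
    """A file could not be parsed; carries the offending line when known."""

    def __init__(self, message, line=None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
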