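"""Exception hierarchy.

Every error raised by the package derives from :class:`BarbendError` so
callers (notably the pipeline stage isolation) can catch package failures
without swallowing programming errors.
"""


class BarbendError(Exception):
    """Base class for all package errors."""


class ParseError(BarbendError):
    """A structure/trajectory file failed to parse; message names the line."""

    def __init__(self, message: str, line_number: int | None = None):
        super().__init__(message)
        self.line_number = line_number


class StructureError(BarbendError):
    """Frames/topology are mutually inconsistent (e.g. atom-count mismatch)."""


class SpecError(BarbendError):
    """A synthetic-data spec is self-inconsistent or physically impossible."""


class ConfigurationError(BarbendError):
    """A selection, residue reference or config key does not resolve."""


class AlignmentError(BarbendError):
    """Frame alignment is degenerate (e.g. collinear membrane points)."""


class FitError(BarbendError):
    """A geometric fit cannot be performed (too few points, all frames bad)."""


class ConstantSeriesError(BarbendError):
    """Pearson correlation is undefined because one series is constant."""
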