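"""Exception hierarchy shared by all workflow programs.

Every exception maps to CLI exit code 2 (usage / I/O / format errors),
mirroring the severity policy where ``error`` findings also exit 2.
"""


class OmdctError(Exception):
    """Base class for all toolkit errors."""


class InputError(OmdctError):
    """Invalid user input: bad accession, missing column, bad option."""


class FormatError(OmdctError):
    """Malformed on-disk artifact: duplicated headers, bad control file."""


class DialectError(FormatError):
    """A table does not satisfy the requirements of its declared dialect."""

    def __init__(self, message: str, missing_columns: list[str] | None = None):
        super().__init__(message)
        self.missing_columns = missing_columns or []


class AcquisitionError(OmdctError):
    """A metadata fetcher or download source failed."""


class FilterError(OmdctError):
    """A filter step could not be applied (e.g. non-numeric cell)."""

    def __init__(self, message: str, code: str = "", step_index: int | None = None):
        super().__init__(message)
        self.code = code
        self.step_index = step_index


class TreatmentError(OmdctError):
    """A treatment template cannot be executed safely."""


class ConcatError(OmdctError):
    """A dataset failed validation and cannot be concatenated."""

    def __init__(self, message: str, report=None):
        super().__init__(message)
        self.report = report
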