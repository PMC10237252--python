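"""Exception hierarchy shared across the package."""

from __future__ import annotations


class MsnsError(Exception):
    """Base class for all package-specific errors."""


class UnknownParameterError(MsnsError):
    """A rubric parameter name that is not one of the eight MSNS parameters."""

    def __init__(self, parameter: str):
        self.parameter = parameter
        super().__init__(f"unknown MSNS parameter: {parameter!r}")


class ValidationError(MsnsError):
    """One or more field-level problems on a neonate record.

    ``issues`` is a list of ``(record_id, field, message)`` tuples so callers
    can report every problem on a record at once.
    """

    def __init__(self, issues):
        self.issues = list(issues)
        lines = "; ".join(f"[{rid}] {field}: {msg}" for rid, field, msg in self.issues)
        super().__init__(f"validation failed: {lines}")
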