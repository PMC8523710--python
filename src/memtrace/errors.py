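"""Exception hierarchy.

Validation errors (bad specs, malformed tables, incompatible shapes) are kept
separate from runtime/numerical errors so the CLI can map them to distinct
exit codes.
"""


class MemtraceError(Exception):
    """Base class for all package errors."""


class ValidationError(MemtraceError, ValueError):
    """Invalid specification, configuration, or input table."""


class DesignError(MemtraceError):
    """Design-matrix problem (rank deficiency, collinearity, bad events)."""

    def __init__(self, msg, columns=None):
        super().__init__(msg)
        self.columns = list(columns) if columns is not None else []


class DegenerateDataError(MemtraceError):
    """Data without enough variation to support the requested statistic."""
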