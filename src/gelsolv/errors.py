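"""Exception hierarchy shared across gelsolv modules."""


class GelsolvError(Exception):
    """Base class for all gelsolv errors."""


class SchemaError(GelsolvError):
    """A tabular input does not match the expected column schema."""


class ValidationError(GelsolvError, ValueError):
    """A value violates a physical or structural constraint."""


class UnknownGroupError(GelsolvError, LookupError):
    """A composition references group names absent from the contribution table."""

    def __init__(self, names):
        self.names = sorted(names)
        super().__init__(
            "unknown group name(s) not in contribution table: "
            + ", ".join(self.names)
        )


class MissingTimepointError(GelsolvError, LookupError):
    """A requested time was never sampled (exact-match lookup policy)."""


class InsufficientDataError(GelsolvError):
    """Too few data points for the requested analysis."""
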