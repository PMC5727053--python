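"""Exception hierarchy for the dfhm package."""


class DfhmError(Exception):
    """Base class for all dfhm errors."""


class FormatError(DfhmError):
    """A file could not be parsed as the declared format."""


class ValidationError(DfhmError, ValueError):
    """Input violates a documented precondition or invariant."""


class MissingChannelError(ValidationError):
    """A montage channel is absent from a recording."""

    def __init__(self, labels):
        self.labels = tuple(labels)
        super().__init__(f"recording is missing montage channel(s): {', '.join(self.labels)}")


class DegenerateBaselineError(ValidationError):
    """A baseline electrode/band has zero variance, so z-scores are undefined."""

    def __init__(self, entries):
        self.entries = tuple(entries)
        names = ", ".join(f"{ch}/{band}" for ch, band in self.entries)
        super().__init__(f"degenerate baseline (sd = 0) at: {names}")


class IcaError(DfhmError):
    """Independent component analysis failed; raw data is never passed through silently."""
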