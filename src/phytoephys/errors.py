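"""Exception hierarchy for the phytoephys pipeline."""


class PhytoephysError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(PhytoephysError, ValueError):
    """An argument violates a documented precondition or type invariant."""


class FormatError(PhytoephysError, ValueError):
    """A trace file or sidecar is malformed.

    Carries the offending line number when known.
    """

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line


class AlignmentError(PhytoephysError, RuntimeError):
    """Alignment point undefined (flat derivative, degenerate window)."""


class FeatureUndefinedError(PhytoephysError, RuntimeError):
    """A waveform statistic is undefined on this input (e.g. no second
    half-amplitude crossing on a truncated record)."""


class UndefinedSNRError(PhytoephysError, RuntimeError):
    """Baseline variance is zero; SNR would be infinite."""
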