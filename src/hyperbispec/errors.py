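"""Exception hierarchy.

All package errors derive from :class:`HyperbispecError` so callers can
catch everything from one root; the leaves distinguish user-facing failure
modes (bad files, bad arguments, numerically infeasible filters).
"""


class HyperbispecError(Exception):
    """Root of the package exception hierarchy."""


class FormatError(HyperbispecError):
    """A file failed to parse; the message names the offending field/row."""


class UnsupportedFormatError(FormatError):
    """Unknown dialect or container version."""


class MissingChannelError(HyperbispecError, KeyError):
    """A channel label was not found in a recording or montage."""


class AlignmentError(HyperbispecError, ValueError):
    """Two objects that must share an axis (time grid, bins) do not."""


class EmptyWindowError(HyperbispecError, ValueError):
    """No analysis window could be extracted (too short or fully masked)."""


class InfeasibleFilterError(HyperbispecError, ArithmeticError):
    """The H-infinity recursion lost positive-definiteness.

    Carries the first failing sample index as ``sample``.
    """

    def __init__(self, sample: int, message: str | None = None):
        self.sample = sample
        super().__init__(message or f"H-infinity filter infeasible at sample {sample}")


class ConfigError(HyperbispecError, ValueError):
    """Pipeline configuration failed schema validation."""
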