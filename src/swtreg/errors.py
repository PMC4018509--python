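"""Exception types raised across the package."""


class SwtRegError(Exception):
    """Base class for all package-specific errors."""


class UnsupportedFormatError(SwtRegError):
    """Input file exists but is not a supported grayscale image."""


class DegenerateOverlapError(SwtRegError):
    """A transformed image pair has no valid overlapping pixels."""


class DegenerateEntropyError(SwtRegError):
    """Both images are constant: the joint entropy is zero and NMI undefined."""


class BracketingError(SwtRegError):
    """A 1D line search failed to bracket a minimum within its budget."""


class ObjectiveError(SwtRegError):
    """The objective returned a non-finite value during optimization."""

    def __init__(self, message, point=None):
        super().__init__(message)
        self.point = point
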