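"""Exception hierarchy shared across the package."""


class SlowstepError(Exception):
    """Base class for all package-specific errors."""


class InputError(SlowstepError, ValueError):
    """Invalid argument values or mismatched shapes."""


class DegenerateInputError(InputError):
    """Input that makes the requested computation undefined (e.g. zero gravity)."""


class FormatError(InputError):
    """Malformed session file, sidecar or configuration document."""


class BoundaryError(InputError):
    """A requested window extends past the signal bounds."""


class InsufficientDataError(SlowstepError):
    """Too few training examples to fit a detector."""


class UndefinedMetricError(SlowstepError):
    """A metric is undefined for the given inputs (e.g. recall with no truth steps)."""
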