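"""Exception hierarchy used across the package."""


class ParkscreenError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ParkscreenError):
    """A file does not conform to the documented dialect (missing column,
    non-monotone time stamps, malformed sidecar)."""


class ValidationError(ParkscreenError):
    """A value violates a domain contract (enum, range, required input)."""


class InsufficientDataError(ParkscreenError):
    """Not enough usable data to compute the requested quantity
    (e.g. no QC-passing trial for a participant/hand/task)."""
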