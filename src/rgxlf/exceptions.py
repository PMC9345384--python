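"""Exception hierarchy for rgxlf."""


class RgxlfError(Exception):
    """Base class for all rgxlf errors."""


class InvalidParameterError(RgxlfError, ValueError):
    """A parameter violates its contract (e.g. non-positive period, K >= N)."""


class ConfigurationError(RgxlfError, ValueError):
    """A configuration object is internally inconsistent."""


class GeometryError(RgxlfError, ValueError):
    """Acquisition geometry does not support the requested operation."""


class BoundsError(RgxlfError, ValueError):
    """An ROI or index range falls outside the data."""


class DegenerateTraceError(RgxlfError, ValueError):
    """A trace cannot be normalized (max equals min over the valid range)."""


class NoHeartRateError(RgxlfError, ValueError):
    """The cardiac search band is empty after harmonic exclusion."""


class FitError(RgxlfError, RuntimeError):
    """Nonlinear fit failed to converge; carries initialization and residuals."""

    def __init__(self, message, init=None, residuals=None):
        super().__init__(message)
        self.init = init
        self.residuals = residuals


class FormatError(RgxlfError, ValueError):
    """An on-disk projection stack and its sidecar metadata disagree."""
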