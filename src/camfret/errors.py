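"""Exception hierarchy.

All user-facing failures derive from :class:`CamfretError` so callers can
catch one type at pipeline boundaries while tests can assert on the
specific subclass.
"""


class CamfretError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(CamfretError, ValueError):
    """An argument violates a documented precondition."""


class ValidationError(CamfretError, ValueError):
    """A parameter object violates its invariants."""


class DataError(CamfretError):
    """Input data are structurally or numerically unusable."""


class StatsError(CamfretError):
    """A statistical design cannot be evaluated on the given data."""


class CalibrationError(CamfretError):
    """Preset calibration failed to reach its targets.

    Carries the per-metric residual report in :attr:`residuals`.
    """

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = dict(residuals or {})
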