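"""Exception hierarchy for helmkit.

Every error raised by the library derives from :class:`HelmkitError` so
callers can catch analysis failures without masking programming errors.
"""


class HelmkitError(Exception):
    """Base class for all helmkit errors."""


class InvalidGridError(HelmkitError):
    """A time grid is malformed (non-positive bin width, stop <= start, ...)."""


class AlignmentError(HelmkitError):
    """Two objects that must share a time grid do not."""


class InvalidModelError(HelmkitError):
    """A decay or anisotropy model violates its physical constraints."""


class UnknownPresetError(HelmkitError):
    """The requested system / excitation / buffer combination is not defined."""


class CalibrationError(HelmkitError):
    """A preset calibration solve failed (target infeasible for the template)."""


class CoverageError(HelmkitError):
    """A wavelength grid does not cover the region an operation needs."""


class WindowRangeError(HelmkitError):
    """A time window or readout point falls outside the measured range."""


class DegenerateSignalError(HelmkitError):
    """No signal above background, so normalisation or fractions are undefined."""


class InsufficientBaselineError(HelmkitError):
    """No pre-rise bins (t < -0.5 ns) available for background estimation."""


class InsufficientDataError(HelmkitError):
    """Too few defined data points for the requested statistic."""


class FitFailureError(HelmkitError):
    """A nonlinear fit did not converge or returned an unphysical result.

    The optional ``diagnostics`` attribute carries the fitter's report.
    """

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


class NoTransitionError(HelmkitError):
    """A melting curve shows no sigmoidal transition to fit."""


class PartitionError(HelmkitError):
    """Photon-budget intervals overlap or fail to cover the full range."""


class MultimodalSpectrumError(HelmkitError):
    """A spectrum crosses its half maximum more than twice; FWHM undefined."""


class MissingInputError(HelmkitError):
    """A required wavelength or channel is absent from the input data set."""


class ParseError(HelmkitError):
    """A tabular file is malformed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number
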