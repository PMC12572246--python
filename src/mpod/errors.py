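"""Exception hierarchy for the mpod package."""


class MpodError(Exception):
    """Base class for all package-specific errors."""


class InvalidModelError(MpodError):
    """Model kind and parameter type do not match, or parameters are invalid."""


class ProfileParseError(MpodError):
    """A radial-profile text file could not be parsed."""


class OutOfBoundsError(MpodError):
    """A requested sample circle or point lies outside the image."""


class ExtrapolationError(MpodError):
    """A resampling grid extends beyond the measured eccentricity range."""


class EmptyWindowError(MpodError):
    """An eccentricity window contains no data points."""


class NonConvergenceError(MpodError):
    """No optimiser start converged.  Carries the best-effort fit in ``result``."""

    def __init__(self, message, result=None):
        super().__init__(message)
        self.result = result


class CohortSpecError(MpodError):
    """A synthetic-cohort specification is infeasible."""


class DegenerateVariableError(MpodError):
    """A variable submitted to factor analysis is constant."""


class CollinearityError(MpodError):
    """The regression design matrix is rank deficient."""
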