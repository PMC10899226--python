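"""Exception hierarchy for audiometric analysis errors.

Every error raised by this package derives from :class:`AudioprofileError`,
so callers can catch one base class at pipeline boundaries while tests can
assert on the specific failure mode.
"""


class AudioprofileError(Exception):
    """Base class for all package errors."""


class SchemaError(AudioprofileError):
    """An input table is missing a required column or has an invalid layout."""


class ParseError(AudioprofileError):
    """A table cell could not be parsed (non-numeric age/threshold, bad label)."""


class ConflictError(AudioprofileError):
    """Duplicate (subject, ear, frequency) rows carry conflicting thresholds."""


class PairingError(AudioprofileError):
    """Left/right records offered for binaural averaging do not belong together."""


class IncompleteAudiogramError(AudioprofileError):
    """A record lacks the frequencies an operation requires."""


class InsufficientDataError(AudioprofileError):
    """Too few observations to fit or estimate."""


class DegenerateDataError(AudioprofileError):
    """Data with no usable variation (constant thresholds, identical ages)."""


class FitFailureError(AudioprofileError):
    """The nonlinear least-squares solver failed to converge.

    Carries the initialization that was used so the failure is reproducible.
    """

    def __init__(self, message: str, init=None):
        super().__init__(message)
        self.init = init


class NoCrossingError(AudioprofileError):
    """A fitted curve never attains the requested level at a positive age."""


class StratificationError(AudioprofileError):
    """A required comparison group is entirely absent from the data."""


class CohortSpecError(AudioprofileError):
    """A synthetic-cohort specification violates its invariants.

    ``violations`` enumerates every failed constraint.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("invalid cohort spec: " + "; ".join(self.violations))
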