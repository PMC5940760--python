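"""Exception hierarchy.

Every failure the analysis chain can signal derives from :class:`SaxsmmError`
so callers (notably the pipeline, which records failed estimators as absent
values) can catch one base class.
"""


class SaxsmmError(Exception):
    """Base class for all package errors."""


class ProfileFormatError(SaxsmmError):
    """A profile file or array violates the scattering-profile contract."""


class GuinierError(SaxsmmError):
    """No acceptable Guinier fit (e.g. no low-angle decay)."""


class InvariantError(SaxsmmError):
    """A scattering invariant could not be computed (range, sign, ...)."""


class EstimatorError(SaxsmmError):
    """A molecular-mass estimator failed or is not applicable."""


class NotTrainedError(SaxsmmError):
    """An empirical model was used before its coefficients were fitted."""


class NoEvidenceError(SaxsmmError):
    """All four estimators failed; the Bayesian combination has no input."""
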