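"""Exception hierarchy.

All package errors derive from :class:`PainBayesError` so callers can catch
one type at pipeline boundaries while tests can assert on specific failures.
"""


class PainBayesError(Exception):
    """Base class for all errors raised by painbayes."""


class ParameterError(PainBayesError, ValueError):
    """A model or grid parameter is outside its admissible domain."""


class InputError(PainBayesError, ValueError):
    """Malformed or insufficient input data (records, labels, vectors)."""


class DegeneratePosteriorError(PainBayesError, ArithmeticError):
    """The unnormalized posterior vanished everywhere.

    Happens only when the uniform prior floor is absent (w = 1) and the
    observation lies implausibly far from both conditioned components.
    """


class ScalingError(InputError):
    """A VAS scaling group has no usable reference (high-stimulus) ratings."""


class DegenerateClusteringError(InputError):
    """Clustering is undefined, e.g. all scores identical."""


class UndefinedTestError(InputError):
    """A rank test has no sampling distribution, e.g. all paired differences zero."""


class UndefinedCorrelationError(InputError):
    """Correlation undefined because one input vector is constant."""
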