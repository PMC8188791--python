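"""Exception hierarchy.

Errors that callers are expected to catch and handle (estimator fallback,
format validation) get their own classes; everything else raises plain
``ValueError``.
"""


class UmiseenError(Exception):
    """Base class for package-specific errors."""


class FormatError(UmiseenError, ValueError):
    """A file violated one of the text-format contracts."""


class DegenerateHistogramError(UmiseenError, ValueError):
    """A copies-per-UMI histogram carries too little information to fit.

    Raised by estimators when a histogram has a single copy level or fewer
    molecules than the stability threshold.  Pipeline callers catch this and
    leave the gene uncorrected.
    """


class EstimatorUnstableError(UmiseenError, RuntimeError):
    """No stable rational approximant could be constructed for a histogram."""


class UndefinedMetricError(UmiseenError, ValueError):
    """A metric was requested on input for which it is undefined (e.g. N=0)."""
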