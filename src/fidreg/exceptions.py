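"""Exception hierarchy for fidreg.

All errors derive from :class:`FidregError` so callers can catch the
package's failures with a single ``except`` clause; the subclasses mirror
the distinct failure modes of the pipeline (bad arguments, broken marker
correspondence, geometric degeneracy, statistical degeneracy).
"""


class FidregError(Exception):
    """Base class for all fidreg errors."""


class InvalidArgumentError(FidregError, ValueError):
    """An argument is out of range, non-finite, or otherwise malformed."""


class InvalidCorrespondenceError(FidregError, ValueError):
    """Two marker clouds cannot be paired (length or id mismatch, n < 3)."""


class DegenerateConfigurationError(FidregError, ValueError):
    """Marker geometry is degenerate (collinear compute group)."""


class DegenerateOrientationError(FidregError, ValueError):
    """Euler decomposition requested too close to gimbal lock."""


class LeakageError(FidregError, ValueError):
    """A validation marker was also used to fit the transform.

    Target registration error is only meaningful on markers held out from
    the fit; any overlap between the compute and validate sets silently
    biases TRE low, so it is treated as a hard failure.
    """


class DegenerateSampleError(FidregError, ValueError):
    """A paired sample has no usable differences (all zero)."""


class MissingBaselineError(FidregError, ValueError):
    """A comparison table was requested without the baseline method's rows."""
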