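"""Exception hierarchy for spheretrack.

All package-specific failures derive from :class:`SphereTrackError` so callers
can catch a single base class; input-validation failures additionally derive
from :class:`ValueError`.
"""


class SphereTrackError(Exception):
    """Base class for all spheretrack errors."""


class InputError(SphereTrackError, ValueError):
    """Malformed or inconsistent caller input."""


class DegenerateGeometryError(SphereTrackError):
    """Point configuration is collinear or otherwise rank-deficient."""


class IllConditionedError(SphereTrackError):
    """Least-squares system is too ill-conditioned to solve reliably."""


class InvalidDepthError(SphereTrackError):
    """A depth sample was zero (the sensor's invalid-pixel code)."""


class InsufficientSpheresError(SphereTrackError):
    """Fewer than three usable sphere candidates in a frame."""


class AmbiguousCorrespondenceError(SphereTrackError):
    """Two distinct sphere assignments explain the data almost equally well."""


class CorrespondenceError(SphereTrackError):
    """No sphere assignment matches the marker's distance pattern."""


class BundleFormatError(SphereTrackError):
    """Frame bundle on disk violates the documented layout."""


class AlignmentError(SphereTrackError):
    """Temporal cross-correlation alignment failed (no overlap / flat signals)."""


class EvaluationError(SphereTrackError):
    """Accuracy evaluation could not be carried out (e.g. untracked reference)."""
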