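"""Exception hierarchy for myofq.

Every failure mode that a caller is expected to handle gets its own class;
``MyofqError`` is the common base so batch drivers can catch everything from
one analysis stage without masking programming errors.
"""


class MyofqError(Exception):
    """Base class for all myofq analysis errors."""


class DegenerateInputError(MyofqError):
    """Input image carries no signal (zero variance / blank frame)."""


class NoMinimumError(MyofqError):
    """A profile has no interior local minimum to report."""


class BandError(MyofqError):
    """Requested frequency band contains no spectral samples."""


class EmptySetError(MyofqError):
    """Peak detection found no cross-sections above threshold."""


class DegenerateTemplateError(MyofqError):
    """Averaged template has a flat radial profile (no measurable range)."""


class NoCrossingError(MyofqError):
    """Radial profile never crosses the diameter threshold downward."""


class SizeError(MyofqError):
    """Image too small for the requested tiling."""


class AnalysisError(MyofqError):
    """Whole-image analysis failed; message lists per-stage/ROI causes."""


class PhantomSpecError(MyofqError):
    """Synthetic-image specification violates its invariants."""


class PlacementError(MyofqError):
    """Disk placement could not satisfy the separation constraint."""
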