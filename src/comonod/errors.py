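"""Exception hierarchy for the comonod package."""


class ComonodError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ComonodError):
    """A run configuration or metadata table is structurally invalid
    (missing column, malformed config file, out-of-range parameter)."""


class RecordValidationError(ComonodError):
    """A single metadata record violates its invariants
    (non-positive altitude or footprint, unreadable image, ...)."""


class ThresholdSelectionError(ComonodError):
    """No binarisation threshold satisfies the compactness criterion for
    an image; the image is skipped and its statistics recorded as NaN."""


class SceneGenerationError(ComonodError):
    """The synthetic-scene rejection sampler could not place the requested
    objects within its retry budget (density infeasible)."""
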