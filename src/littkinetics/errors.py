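"""Exception hierarchy for littkinetics."""


class LittKineticsError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(LittKineticsError):
    """Invalid cohort-simulation configuration (counts, priors, schedule)."""


class CategorizationError(LittKineticsError):
    """A trajectory cannot be categorized (e.g. missing pre- or post-LITT scan)."""


class NormalizationError(LittKineticsError):
    """Degenerate intensity normalization or percent-volume normalization."""


class InsufficientDataError(LittKineticsError):
    """Too few timepoints for the requested model fit."""


class FitFailureError(LittKineticsError):
    """No multi-start initialization converged."""


class GeometryError(LittKineticsError):
    """Images/masks do not share a voxel grid."""


class DegeneratePhantomError(LittKineticsError):
    """Phantom geometry smaller than one voxel."""


class EvaluationError(LittKineticsError):
    """Timepoint-pair evaluation is impossible (e.g. an empty category)."""
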