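"""Exception types raised across the pipeline."""


class GaitCountsError(Exception):
    """Base class for all package-specific errors."""


class TrialTooShortError(GaitCountsError):
    """A trial shorter than twice the trim window cannot be segmented."""


class BelowMinimumSpeedError(GaitCountsError):
    """A walking trial slower than the minimum walking speed (0.41 m/s)."""


class DegenerateLabelsError(GaitCountsError):
    """ROC analysis requires both classes to be present."""


class DegenerateCurveError(GaitCountsError):
    """ROC curve has too few operating points to pick a cut-point."""


class InsufficientClassesError(GaitCountsError):
    """Cut-point calibration requires all four categories in the stratum."""
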