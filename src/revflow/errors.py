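"""Exception hierarchy for the revflow pipeline."""


class RevflowError(Exception):
    """Base class for all revflow errors."""


class ConfigurationError(RevflowError):
    """Invalid phantom or pipeline configuration (geometry out of bounds,
    landmarks outside the centerline range, bad parameter values)."""


class GeometryError(RevflowError):
    """Centerline extraction failed: disconnected mask, seed outside the
    segmentation, or no admissible path between the seeds."""


class TimingError(RevflowError):
    """Cardiac-phase analysis failed: too few frames in the analysis
    window, or a net-flow curve whose peak lies at the final frame so the
    cycle cannot be split into systole and diastole."""
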