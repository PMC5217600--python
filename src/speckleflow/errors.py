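"""Exception types shared across the pipeline."""


class SpeckleflowError(Exception):
    """Base class for all package-specific errors."""


class ScenarioOverflowError(SpeckleflowError):
    """Requested occlusion territory does not fit the hemisphere mask ("scenario-overflow")."""


class UndersampledIntegrationError(SpeckleflowError):
    """Exposure covers too many correlation times for the chosen number of
    sub-integration steps ("undersampled-integration")."""


class EmptyIntervalError(SpeckleflowError):
    """A requested acquisition interval contains no frames ("empty-interval")."""


class DegenerateInputError(SpeckleflowError):
    """An image without texture cannot be registered ("degenerate-input")."""
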