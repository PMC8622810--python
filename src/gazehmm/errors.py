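"""Named exceptions raised across the package."""


class GazeHmmError(ValueError):
    """Base class for all gazehmm errors."""


class ArchetypeLabelError(GazeHmmError):
    """Unknown gaze-archetype label."""


class ConfigError(GazeHmmError):
    """Invalid configuration (probabilities out of range, bad K range, ...)."""


class WindowError(GazeHmmError):
    """Analysis event falls outside the recording span."""


class EmptySequenceError(GazeHmmError):
    """An operation that needs fixations received none."""


class FitError(GazeHmmError):
    """Model fitting could not proceed (no usable sequences, bad K, ...)."""


class ClusteringError(GazeHmmError):
    """HMM clustering could not proceed (fewer models than clusters, ...)."""


class LabelingError(GazeHmmError):
    """Representatives cannot be told apart (dispersion tie) or labels invalid."""


class AnalysisError(GazeHmmError):
    """Invalid input to a statistical operation (zero margins, no probes, ...)."""


class InputValidationError(GazeHmmError):
    """A delimited input file failed schema validation."""
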