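"""Exception hierarchy shared across the pipeline stages."""


class NightglowError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(NightglowError):
    """Input data violates a contract (e.g. DN outside 0..63)."""


class FormatError(NightglowError):
    """A file is not in the expected on-disk format."""


class AlignmentError(NightglowError):
    """Composites in a series do not share a common grid."""


class UndefinedCorrelationError(NightglowError):
    """Pearson correlation is undefined (constant grid on the valid set)."""


class InsufficientOverlapError(NightglowError):
    """Too few jointly valid pixels to evaluate a shift candidate."""


class FitError(NightglowError):
    """Calibration regression could not be fitted."""


class SceneSpecError(NightglowError):
    """A synthetic scene specification violates the method's assumptions."""
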