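"""Exception hierarchy shared across the pipeline."""


class OctadError(Exception):
    """Base class for all package errors."""


class InputError(OctadError):
    """Invalid or unreadable input data."""


class DegenerateInputError(InputError):
    """Input collapses under the requested operation (e.g. all-margin image)."""


class ConfigurationError(OctadError):
    """Configuration values inconsistent with the data they are applied to."""


class ResourceError(OctadError):
    """A required runtime asset (e.g. pretrained weights) is unavailable."""


class TrainingError(OctadError):
    """Optimization diverged or otherwise failed."""


class EvaluationError(OctadError):
    """Metrics requested on inputs that cannot support them."""
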