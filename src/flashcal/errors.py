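"""Exception hierarchy for the dosimetry pipeline.

Everything derives from :class:`FlashcalError` so callers (and the CLI) can
catch pipeline failures without masking programming errors.
"""


class FlashcalError(Exception):
    """Base class for all flashcal errors."""


class DegenerateFitError(FlashcalError, ValueError):
    """Too few samples (or a singular system) for the requested fit."""


class InvalidWindowError(FlashcalError, ValueError):
    """A fit window overlaps the irradiation window or is malformed."""


class InsufficientDataError(FlashcalError, ValueError):
    """An estimator was given fewer points than it needs."""


class InsufficientReplicatesError(FlashcalError, ValueError):
    """Run aggregation requires at least two runs."""


class NonPhysicalValueError(FlashcalError, ValueError):
    """An input or result violates a physical sanity bound."""


class ConfigurationError(FlashcalError, ValueError):
    """Missing or inconsistent configuration (calibration data, files, labels)."""
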