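"""Exception hierarchy for the screening pipeline.

Every error a caller can reasonably branch on has its own class; all
inherit from :class:`FatscreenError` so ``except FatscreenError`` catches
anything the package raises deliberately.
"""


class FatscreenError(Exception):
    """Base class for all package errors."""


class InvalidMeasurementError(FatscreenError, ValueError):
    """A physical measurement (weight, height, dose, enrichment) is invalid."""


class InvalidParameterError(FatscreenError, ValueError):
    """A model parameter (L, M, S, threshold, z-score) is invalid."""


class AgeOutOfRangeError(FatscreenError, ValueError):
    """Requested age lies outside the growth-reference grid."""


class ReferenceIncompleteError(FatscreenError, ValueError):
    """The growth reference lacks a required sex stratum or column."""


class IncompleteRecordError(FatscreenError, ValueError):
    """A record is missing a field required by the requested stage."""


class InconsistentEnrichmentError(FatscreenError, ValueError):
    """Post-dose enrichment below baseline, or similar physical inconsistency."""


class ConfigurationError(FatscreenError, ValueError):
    """A configuration table or option is missing or malformed."""


class DegenerateInputError(FatscreenError, ValueError):
    """Input admits no meaningful answer (e.g. single-class ROC labels)."""


class PipelineError(FatscreenError, RuntimeError):
    """Inconsistent intermediate state inside the analysis pipeline."""
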