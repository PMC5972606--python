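"""Exception hierarchy shared across the package."""


class ClinAnnotateError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ClinAnnotateError):
    """A file does not conform to its expected layout."""


class ValidationError(ClinAnnotateError):
    """Loaded data violates an integrity constraint."""


class ConceptLookupError(ClinAnnotateError, KeyError):
    """A concept id is not present in the terminology."""


class ConfigurationError(ClinAnnotateError):
    """An option value is unknown or inconsistent."""


class StateError(ClinAnnotateError):
    """An operation was invoked before its prerequisite stage ran."""


class IntegrityError(ClinAnnotateError):
    """An annotation or serialized record disagrees with its document text."""


class AlignmentError(ClinAnnotateError):
    """Predictions reference documents absent from the gold corpus."""


class GenerationError(ClinAnnotateError):
    """Synthetic corpus generation parameters are unsatisfiable."""
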