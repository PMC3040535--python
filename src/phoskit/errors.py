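"""Exception hierarchy shared across the package."""


class PhoskitError(Exception):
    """Base class for all package-specific errors."""


class AnnotationError(PhoskitError):
    """An annotation is inconsistent with its protein sequence."""


class MergeConflictError(PhoskitError):
    """Two inputs carry the same accession with different sequences."""


class FormatError(PhoskitError):
    """A file does not conform to the expected format."""


class DatasetError(PhoskitError):
    """A dataset cannot be built or is unusable for training."""


class LayoutMismatchError(PhoskitError):
    """Feature layout of the input does not match the model's layout."""


class TrainingError(PhoskitError):
    """Training preconditions are not met."""


class MissingTrackError(PhoskitError):
    """A required per-residue score track is absent and no provider is configured."""
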