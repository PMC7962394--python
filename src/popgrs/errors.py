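"""Exception hierarchy shared across the package."""


class PopgrsError(Exception):
    """Base class for all popgrs errors."""


class FormatError(PopgrsError):
    """An input file does not conform to the expected dialect."""


class ValidationError(PopgrsError):
    """A value violates a domain invariant (range, type, sign)."""


class HarmonizationError(PopgrsError):
    """A reported allele cannot be reconciled with the ref/alt pair."""


class ConfigurationError(PopgrsError):
    """A run configuration is inconsistent or incomplete."""


class DegenerateInputError(PopgrsError):
    """An input is structurally valid but carries no usable information."""


class DataUnavailableError(PopgrsError):
    """A reference dataset is not bundled with the package."""
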