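"""Exception hierarchy shared across the package."""


class PanstrainError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PanstrainError):
    """A file does not conform to its declared format."""


class CoordinateError(PanstrainError):
    """Feature coordinates fall outside the parent sequence."""


class ConsistencyError(PanstrainError):
    """Cross-references between objects do not line up."""


class MetadataError(PanstrainError):
    """Required metadata fields are missing or malformed."""


class LabelingError(PanstrainError):
    """A sequence row cannot be mapped to a labeled genome."""


class AlphabetError(PanstrainError):
    """A residue is absent from the scoring scheme's alphabet."""


class SaturationError(PanstrainError):
    """A distance correction is undefined for the observed divergence."""


class ConfigError(PanstrainError):
    """A configuration value is out of range or inconsistent."""


class StageError(PanstrainError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
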