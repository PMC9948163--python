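"""Exception hierarchy shared across the pipeline stages."""


class ChemLandscapeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ChemLandscapeError):
    """An input table does not have the expected shape (e.g. missing column)."""


class CurationError(ChemLandscapeError):
    """A record cannot be curated (bad units, non-positive IC50, parse failure)."""


class ConfigError(ChemLandscapeError):
    """A configuration value is invalid or internally inconsistent."""


class DecompositionError(ChemLandscapeError):
    """R-group decomposition failed (member does not contain the scaffold)."""


class StageError(ChemLandscapeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
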