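"""Exception hierarchy shared across the package."""


class PatchflowError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PatchflowError):
    """Unreadable file or unsupported image format."""


class ConfigError(PatchflowError):
    """Invalid or incomplete experiment configuration."""


class ManifestError(PatchflowError):
    """Malformed subject manifest (schema, duplicates, missing files)."""


class CohortSizeError(PatchflowError):
    """Too few subjects for the requested cross-validation layout."""


class NormalizationError(PatchflowError):
    """Degenerate input to an intensity normalization step."""


class DegenerateInputError(PatchflowError):
    """Input without enough structure for the operation (e.g. constant values)."""
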