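"""Exception hierarchy for varmatch."""


class VarmatchError(Exception):
    """Base class for all varmatch errors."""


class SchemaError(VarmatchError):
    """A table is missing required columns or has an unusable layout."""


class ValidationError(VarmatchError):
    """Content-level problem: duplicate names, empty labels, unknown variables."""


class ConfigurationError(VarmatchError):
    """Invalid or unavailable configuration (e.g., unknown embedding backend)."""
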