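"""Exception hierarchy shared across the pipeline."""


class FormatError(ValueError):
    """A file or array does not follow the expected on-disk dialect."""


class SchemaError(ValueError):
    """A table is missing required columns or carries invalid categories."""


class PackingError(RuntimeError):
    """Hard-core cell placement could not reach the requested density."""


class ConfigurationError(ValueError):
    """A configuration value is inconsistent (e.g. non-positive diffusivity)."""
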