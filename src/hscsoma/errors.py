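"""Exception types."""


class ParameterError(ValueError):
    """A numeric parameter is outside its valid domain."""


class ConfigError(ValueError):
    """A configuration file or preset failed validation.

    Messages name the offending field path (e.g. ``dfe.sigma``).
    """


class OverlapUndefinedError(RuntimeError):
    """Overlap statistics requested on an empty plausible range."""
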