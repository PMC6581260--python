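"""Exception types used across the package."""


class ConfigurationError(ValueError):
    """A model, task or scenario configuration is inconsistent."""
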