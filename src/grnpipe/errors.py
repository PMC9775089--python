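class ConfigError(ValueError):
    """A configuration value violates a documented bound."""
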