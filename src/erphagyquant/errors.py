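"""Exception types shared across the pipeline."""


class ConfigError(ValueError):
    """A simulation or analysis configuration field is invalid."""


class DesignError(ValueError):
    """A plex design or allelic design is inconsistent with the data."""
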