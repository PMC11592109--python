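"""Exception types shared across modules."""


class ConfigError(ValueError):
    """A configuration field is invalid; the message names the field."""


class ChannelError(ValueError):
    """The requested image channel does not exist."""
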