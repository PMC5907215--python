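"""Exception types shared across the package."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending location."""
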