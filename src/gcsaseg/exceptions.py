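"""Package-level error types."""


class ShapeError(ValueError):
    """An array's shape violates an operation's contract."""


class ConfigurationError(ValueError):
    """A configuration value is structurally invalid (e.g. indivisible widths)."""
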