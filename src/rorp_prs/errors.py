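"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A simulation or run configuration violates its invariants."""


class InputError(ValueError):
    """An input table or matrix violates its contract."""
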