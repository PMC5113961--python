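"""Exception types raised across the pipeline."""


class ConfigurationError(ValueError):
    """A community or run configuration violates its invariants."""


class FormatError(ValueError):
    """An input file does not conform to its declared dialect."""


class InputError(ValueError):
    """Inputs to an operation are inconsistent or out of range."""


class NormalizationError(ValueError):
    """Per-sample normalization is impossible (e.g. zero recA count)."""
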